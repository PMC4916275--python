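"""Recursive composition of association modules over Markov blankets.

A composite network carries one association module per random variable
of a discrete graphical model.  The output population nu^k of module k
(one neuron per non-zero value of y^k) doubles as the input population
of every module whose variable has y^k in its input set — the neurons
are shared, not copied.  During training every module learns, from the
same example stream, a generative model of the marginal
p*(y^k, y^B(k)) over its variable and its Markov blanket; after
training the network's spontaneous activity samples an approximation
of p*(y), and clamping evidence neurons turns the spontaneous dynamics
into a sampler of the conditional posterior.

State decoding follows the neural-sampling convention: a spike of the
neuron coding y^k = l sets the variable to l for one coding window tau,
after which it falls back to 0 ("no recent spike").
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .genmodel import DistributionTable, kl_objective
from .module import (
    Checkpoint,
    I_EXCITE,
    I_GATE,
    I_INHIBIT,
    ModuleIndex,
    ModuleParams,
    ModuleSpec,
    VariableSpec,
    build_module,
    default_b_minus,
)
from .network import NetworkSpec, NeuronSpec, SpikeRecord
from .plasticity import PlasticityConfig
from .simulator import Simulator

__all__ = [
    "GraphicalModelSpec",
    "markov_blanket",
    "CompositeNetwork",
    "NetworkFitResults",
    "results_from_thetas",
    "constructed_network",
    "StateTrace",
    "decode_state",
    "sample_stationary",
    "infer_posterior",
    "exact_posterior",
    "estimate_rates",
]


class GraphicalModelSpec:
    """A discrete graphical model: Bayesian network or explicit joint.

    Parameters
    ----------
    variables : list of (name, cardinality) or VariableSpec
    parents : dict, optional
        For a Bayesian network: variable name -> list of parent names.
    cpts : dict, optional
        name -> array of shape (card(parent1), ..., card(name)); the
        last axis is the variable itself and rows sum to 1.  Variables
        without parents carry their prior as a 1-d array.
    joint : DistributionTable, optional
        Alternatively an explicit joint over all variables (values
        1..M); subsumes small Markov random fields and factor graphs.
    input_sets : dict, optional
        Per-variable override of the module input set; must contain the
        minimal Markov blanket.
    """

    def __init__(self, variables, parents=None, cpts=None, joint=None,
                 input_sets=None):
        self.variables = [
            v if isinstance(v, VariableSpec) else VariableSpec(*v)
            for v in variables
        ]
        self.names = [v.name for v in self.variables]
        self.card = {v.name: v.cardinality for v in self.variables}
        self.input_sets = {k: list(v) for k, v in (input_sets or {}).items()}
        if joint is not None:
            if parents is not None or cpts is not None:
                raise ValueError("give either a joint or a Bayesian network")
            self.parents = None
            self.cpts = None
            self._joint = joint.marginal(self.names)
        else:
            if parents is None or cpts is None:
                raise ValueError("need parents and cpts (or a joint)")
            self.parents = {k: list(v) for k, v in parents.items()}
            for v in self.names:
                self.parents.setdefault(v, [])
            self._check_acyclic()
            self.cpts = {}
            for name in self.names:
                cpt = np.asarray(cpts[name], dtype=float)
                shape = tuple(
                    self.card[p] for p in self.parents[name]
                ) + (self.card[name],)
                if cpt.shape != shape:
                    raise ValueError(
                        f"CPT for {name}: shape {cpt.shape} != {shape}"
                    )
                if np.any(np.abs(cpt.sum(axis=-1) - 1.0) > 1e-9):
                    raise ValueError(f"CPT rows for {name} must sum to 1")
                self.cpts[name] = cpt
            self._joint = None
        for k, vs in self.input_sets.items():
            mb = set(self.markov_blanket(k)) if self.parents else set()
            if self.parents is not None and not mb <= set(vs):
                raise ValueError(
                    f"input set for {k} must contain its Markov blanket"
                )

    def _check_acyclic(self):
        seen: dict[str, int] = {}

        def visit(v):
            state = seen.get(v, 0)
            if state == 1:
                raise ValueError("Bayesian network has a cycle")
            if state == 2:
                return
            seen[v] = 1
            for p in self.parents[v]:
                visit(p)
            seen[v] = 2

        for v in self.names:
            visit(v)

    def markov_blanket(self, name: str) -> list:
        """Parents, children and coparents of ``name`` (minimal blanket)."""
        if name not in self.card:
            raise KeyError(f"unknown variable {name}")
        if self.parents is None:
            return [n for n in self.names if n != name]
        blanket = set(self.parents[name])
        for child, ps in self.parents.items():
            if name in ps:
                blanket.add(child)
                blanket.update(p for p in ps if p != name)
        blanket.discard(name)
        return [n for n in self.names if n in blanket]

    def module_inputs(self, name: str) -> list:
        if name in self.input_sets:
            return list(self.input_sets[name])
        return self.markov_blanket(name)

    def joint(self) -> DistributionTable:
        """Exact joint over all variables (values 1..M) by enumeration."""
        if self._joint is not None:
            return self._joint
        cards = [self.card[n] for n in self.names]
        if np.prod(cards) > 10**6:
            raise ValueError("joint too large to enumerate")
        p = np.zeros(tuple(cards))
        for combo in itertools.product(*[range(1, c + 1) for c in cards]):
            assignment = dict(zip(self.names, combo))
            prob = 1.0
            for name in self.names:
                idx = tuple(
                    assignment[par] - 1 for par in self.parents[name]
                ) + (assignment[name] - 1,)
                prob *= self.cpts[name][idx]
            p[tuple(v - 1 for v in combo)] = prob
        self._joint = DistributionTable(
            [(n, list(range(1, self.card[n] + 1))) for n in self.names], p
        )
        return self._joint


def markov_blanket(gm: GraphicalModelSpec, name: str) -> list:
    return gm.markov_blanket(name)


def exact_posterior(gm: GraphicalModelSpec, evidence: dict) -> dict:
    """Exact conditional marginals p(y^k | evidence) by enumeration."""
    joint = gm.joint()
    table = joint.condition(evidence) if evidence else joint
    out = {}
    for name in table.names:
        out[name] = table.marginal([name]).probs
    return out


# ----------------------------------------------------------------------
# network construction
# ----------------------------------------------------------------------


class CompositeIndex:
    """Bookkeeping for a composite network inside one NetworkSpec."""

    def __init__(self):
        self.nu = {}  # (variable name, value) -> neuron id
        self.modules = {}  # variable name -> ModuleIndex

    def variables(self):
        return list(self.modules)

    def nu_of(self, name: str) -> dict:
        return {
            l: nid for (n, l), nid in self.nu.items() if n == name
        }

    def legend_dumps(self) -> str:
        rows = []
        for (n, l), nid in sorted(self.nu.items()):
            rows.append((nid, f"nu[{n}={l}]"))
        for name, midx in self.modules.items():
            for (l, j), nid in sorted(midx.alpha.items()):
                rows.append((nid, f"alpha[{name}][{name}={l}][j={j}]"))
            for k, nid in enumerate(midx.inhibitory):
                rows.append((nid, f"inh[{name}][{k}]"))
        out = ["# neuron_id\trole"]
        out += ["%d\t%s" % r for r in sorted(rows)]
        return "\n".join(out) + "\n"


class CompositeNetwork:
    """Model object: one learning module per variable of a graphical model.

    Parameters
    ----------
    gm : GraphicalModelSpec
    hidden : int or dict
        Hidden neurons per subpopulation (per variable when a dict).
    params : ModuleParams or dict, optional
    plasticity : dict, optional
        Per-variable PlasticityConfig; defaults are derived per module
        from the structure (bias offset from the input cardinalities).
    """

    def __init__(self, gm, hidden=2, params=None, plasticity=None):
        self.gm = gm
        self.module_specs: dict[str, ModuleSpec] = {}
        for var in gm.variables:
            name = var.name
            inputs = [
                VariableSpec(n, gm.card[n]) for n in gm.module_inputs(name)
            ]
            if isinstance(params, dict):
                p = params.get(name) or ModuleParams()
            else:
                p = params or ModuleParams()
            cfg = (plasticity or {}).get(name) if plasticity else None
            self.module_specs[name] = ModuleSpec(
                inputs=inputs,
                output=var,
                hidden=(
                    hidden.get(name, 2) if isinstance(hidden, dict) else hidden
                ),
                params=p,
                plasticity=cfg,
            )

    def build(self, seed: int = 0):
        """Create the full NetworkSpec with shared nu populations."""
        net = NetworkSpec()
        index = CompositeIndex()
        # output populations first: shared principal neurons
        for var in self.gm.variables:
            p = self.module_specs[var.name].params
            for l in range(1, var.cardinality + 1):
                index.nu[(var.name, l)] = net.add_neuron(
                    NeuronSpec(
                        bias=p.b_pp,
                        refractory=p.tau,
                        name=f"nu[{var.name}={l}]",
                    )
                )
        ss = np.random.SeedSequence(int(seed))
        mod_seeds = ss.generate_state(len(self.gm.variables))
        for var, mseed in zip(self.gm.variables, mod_seeds):
            spec = self.module_specs[var.name]
            in_ids = {}
            for i, iv in enumerate(spec.inputs):
                for m in range(1, iv.cardinality + 1):
                    in_ids[(i, m)] = index.nu[(iv.name, m)]
            out_ids = {
                l: index.nu[(var.name, l)]
                for l in range(1, var.cardinality + 1)
            }
            _, midx = build_module(
                spec,
                seed=int(mseed),
                net=net,
                input_neuron_ids=in_ids,
                output_neuron_ids=out_ids,
            )
            index.modules[var.name] = midx
        return net, index

    # -- training -------------------------------------------------------

    def fit(
        self,
        duration: float = 1200.0,
        seed: int = 0,
        checkpoint_every: float = 60.0,
        dt_example: float = 0.1,
        examples=None,
    ) -> "NetworkFitResults":
        from .experiments import sample_examples

        n_slots = int(round(duration / dt_example))
        joint = self.gm.joint()
        if examples is None:
            examples = sample_examples(
                joint,
                n_slots,
                seed=np.random.SeedSequence(
                    [int(seed), 0xE85]
                ).generate_state(1)[0],
            )
        net, index = self.build(seed=seed)
        pcfg = {}
        for name, midx in index.modules.items():
            cfg = self.module_specs[name].plasticity
            for nid in midx.alpha.values():
                pcfg[nid] = cfg
        sim = Simulator(
            net,
            seed=np.random.SeedSequence(
                [int(seed), 0xD11E]
            ).generate_state(1)[0],
            plasticity=pcfg,
            record=False,
        )
        trajectories = {
            name: [
                Checkpoint(
                    0.0, midx.weight_arrays(sim), midx.bias_array(sim)
                )
            ]
            for name, midx in index.modules.items()
        }
        n_check = int(round(duration / checkpoint_every))
        slots_per_check = int(round(checkpoint_every / dt_example))
        slot = 0
        for _ in range(n_check):
            events = []
            for s in range(slots_per_check):
                t0 = (slot + s) * dt_example
                t1 = t0 + dt_example
                deltas_on, deltas_off = [], []
                ex = examples[slot + s]
                for var in self.gm.variables:
                    v = int(ex[var.name])
                    for l in range(1, var.cardinality + 1):
                        amp = I_EXCITE if l == v else I_INHIBIT
                        nid = index.nu[(var.name, l)]
                        deltas_on.append((nid, amp))
                        deltas_off.append((nid, -amp))
                    midx = index.modules[var.name]
                    for (l, j), nid in midx.alpha.items():
                        if l != v:
                            deltas_on.append((nid, I_GATE))
                            deltas_off.append((nid, -I_GATE))
                events.append((t0, deltas_on))
                events.append((t1, deltas_off))
            sim.add_current_events(events)
            slot += slots_per_check
            sim.run_until(slot * dt_example)
            sim.commit_biases()
            for name, midx in index.modules.items():
                trajectories[name].append(
                    Checkpoint(
                        slot * dt_example,
                        midx.weight_arrays(sim),
                        midx.bias_array(sim),
                    )
                )
        return NetworkFitResults(
            model=self, trajectories=trajectories, index=index, seed=seed
        )


def results_from_thetas(model: "CompositeNetwork", thetas: dict):
    """Wrap analytically set parameters as (unfitted) network results.

    ``thetas`` maps each variable name to a Theta whose hidden counts
    match the model's module specs.  The inverse weight map is applied
    and the parameters are installed as a single checkpoint, so the
    whole sampling/inference surface works on constructed networks —
    the oracle route for verifying the sampler against a known target.
    """
    from .genmodel import weights_from_theta

    net, index = model.build(seed=0)
    trajectories = {}
    for name, midx in index.modules.items():
        th = thetas[name]
        spec = model.module_specs[name]
        if th.J != spec.hidden:
            raise ValueError(
                f"hidden counts of theta for {name} ({th.J}) do not "
                f"match the module spec ({spec.hidden})"
            )
        weights, biases = weights_from_theta(th)
        trajectories[name] = [Checkpoint(0.0, weights, biases)]
    return NetworkFitResults(model, trajectories, index)


def constructed_network(
    gm: GraphicalModelSpec,
    eps: float = 0.02,
    kernel: str = "rectangular",
    params: ModuleParams | None = None,
    excitability_shift: float = -6.0,
):
    """Point-mass construction of a sampling network for ``gm``.

    Each module's parameters are set analytically from the exact
    blanket marginal (one hidden component per input assignment), so
    the network's stationary distribution approximates the target to
    within the construction error O(eps).  Returns
    ``(NetworkFitResults, thetas)``.

    ``excitability_shift`` is subtracted from every hidden bias after
    the inverse weight map.  It rescales all of a module's intensities
    by a common factor — leaving the sampled conditionals untouched —
    and sets the timescale of the release races: with the raw mapping
    the hidden potentials are so large that all modules fire in
    lock-step 15 ms rounds and, under the half-open PSP windows,
    resample at the very instant their inputs expire.  A shift of -6
    spreads the firing by tens of microseconds, which restores the
    asynchronous (Gibbs-like) updating the sampling theory assumes
    while keeping the zero-state dwell negligible.
    """
    from .genmodel import construct_theta

    joint = gm.joint()
    thetas = {}
    hidden = {}
    for var in gm.variables:
        name = var.name
        inputs = gm.module_inputs(name)
        marg = joint.marginal([name] + inputs)
        th = construct_theta(marg, eps=eps, output_name=name)
        thetas[name] = th
        hidden[name] = th.J
    base = params or ModuleParams()
    from dataclasses import replace as _replace
    from .kernels import PSPKernel

    mp = _replace(base, epsp=PSPKernel(kind=kernel, tau=base.tau))
    model = CompositeNetwork(gm, hidden=hidden, params=mp)
    results = results_from_thetas(model, thetas)
    if excitability_shift:
        for name in results.trajectories:
            cp = results.trajectories[name][0]
            results.trajectories[name][0] = Checkpoint(
                cp.t, cp.weights, cp.biases + excitability_shift
            )
    return results, thetas


class NetworkFitResults:
    """Trained composite network plus sampling-based inference."""

    def __init__(self, model, trajectories, index, seed=None):
        self.model = model
        self.trajectories = trajectories
        self.index = index
        self.seed = seed

    @property
    def gm(self) -> GraphicalModelSpec:
        return self.model.gm

    def theta(self, name: str, k: int = -1):
        cp = self.trajectories[name][k]
        return self.index.modules[name].theta(cp.weights, cp.biases)

    @property
    def checkpoint_times(self):
        any_name = next(iter(self.trajectories))
        return [cp.t for cp in self.trajectories[any_name]]

    def marginal_target(self, name: str) -> DistributionTable:
        spec = self.model.module_specs[name]
        names = [name] + [v.name for v in spec.inputs]
        return self.gm.joint().marginal(names)

    def module_kl_curves(self) -> dict:
        """Analytic KL(p*_k || p_k(theta_k)) per module per checkpoint."""
        out = {}
        for name, traj in self.trajectories.items():
            tgt = self.marginal_target(name)
            midx = self.index.modules[name]
            out[name] = np.array(
                [
                    kl_objective(midx.theta(cp.weights, cp.biases), tgt)["U"]
                    for cp in traj
                ]
            )
        return out

    def network_objective_curve(self) -> np.ndarray:
        curves = self.module_kl_curves()
        return np.sum(list(curves.values()), axis=0)

    def frozen_simulator(self, seed: int = 0, k: int = -1, record=True):
        """Simulator of the trained network with plasticity off."""
        net, index = self.model.build(seed=0)
        sim = Simulator(net, seed=seed, record=record)
        values = sim.weights()
        biases = sim.biases()
        for name, midx in index.modules.items():
            cp = self.trajectories[name][k]
            for i, var in enumerate(self.model.module_specs[name].inputs):
                for m in range(1, var.cardinality + 1):
                    for c in range(len(midx.comp)):
                        values[midx.syn[(i, m, c)]] = cp.weights[i][m - 1, c]
            for c, lj in enumerate(midx.comp):
                biases[midx.alpha[lj]] = cp.biases[c]
        sim.set_weights(values)
        sim.set_biases(biases)
        return sim, index

    def sample_stationary(
        self, duration: float = 300.0, burn_in: float = 20.0, seed: int = 0,
        checkpoint: int = -1
    ):
        """Spontaneous-activity histogram of decoded network states."""
        sim, index = self.frozen_simulator(seed=seed, k=checkpoint)
        return sample_stationary(
            sim, index, self.gm, duration=duration, burn_in=burn_in, seed=seed
        )

    def sampled_network_kl(
        self,
        checkpoints=(0, -1),
        duration: float = 300.0,
        burn_in: float = 20.0,
        seed: int = 0,
    ):
        """Network-level KL estimated by sampling at selected checkpoints.

        For each checkpoint the network is frozen at those parameters,
        run spontaneously, and KL(empirical decoded distribution ||
        target joint) is computed from the time-weighted histogram.
        A finite-sampling estimate: with an n-state model the error
        scale is about sqrt(n / samples), reported alongside.
        """
        target = self.gm.joint()
        times = self.checkpoint_times
        out = {}
        for k in checkpoints:
            res = self.sample_stationary(
                duration=duration, burn_in=burn_in, seed=seed, checkpoint=k
            )
            kl, infinite = res["table"].kl_from(target)
            n_states = target.probs.size
            n_samples = (duration - burn_in) / 0.015
            out[times[k]] = {
                "kl": kl,
                "infinite": infinite,
                "zero_fraction": res["zero_fraction"],
                "sampling_error_scale": math.sqrt(n_states / n_samples),
            }
        return out

    def infer(
        self, evidence: dict, duration: float = 0.4, seed: int = 0,
        burn_in: float = 0.0
    ):
        sim, index = self.frozen_simulator(seed=seed)
        return infer_posterior(
            sim, index, self.gm, evidence, duration=duration, seed=seed,
            burn_in=burn_in
        )

    def plot_kl(self, ax=None):
        """Per-module KL curves and their sum over the checkpoints."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ts = self.checkpoint_times
        for name, curve in self.module_kl_curves().items():
            ax.plot(ts, curve, label=name)
        ax.plot(ts, self.network_objective_curve(), "k--", label="total")
        ax.set_xlabel("training time [s]")
        ax.set_ylabel("KL [nats]")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = ["Composite network fit", "=" * 58]
        lines.append(
            "variables: "
            + ", ".join(
                f"{v.name}(1..{v.cardinality})" for v in self.gm.variables
            )
        )
        for name, spec in self.model.module_specs.items():
            lines.append(
                f"  module {name}: inputs "
                + "{"
                + ", ".join(v.name for v in spec.inputs)
                + "}"
                + f", hidden {spec.hidden}"
            )
        kls = self.module_kl_curves()
        lines.append("-" * 58)
        lines.append("analytic KL(p*_k || p_k(theta_k)) [nats]:")
        for name, curve in kls.items():
            lines.append(
                f"  {name}: initial {curve[0]:.4f} -> final {curve[-1]:.4f}"
            )
        total = self.network_objective_curve()
        lines.append(
            f"network objective: initial {total[0]:.4f} -> final "
            f"{total[-1]:.4f}"
        )
        return "\n".join(lines)


# ----------------------------------------------------------------------
# state decoding
# ----------------------------------------------------------------------


@dataclass
class StateTrace:
    """Piecewise-constant decoded assignment per variable over time.

    ``breaks`` has length B+1; ``states[b]`` is the assignment dict on
    ``[breaks[b], breaks[b+1])``.
    """

    breaks: np.ndarray
    states: list

    def at(self, t: float) -> dict:
        b = int(np.searchsorted(self.breaks, t, side="right") - 1)
        b = min(max(b, 0), len(self.states) - 1)
        return self.states[b]

    def dumps(self) -> str:
        names = list(self.states[0])
        out = ["# t_start\tt_end\t" + "\t".join(names)]
        for b, st in enumerate(self.states):
            out.append(
                "%.6f\t%.6f\t" % (self.breaks[b], self.breaks[b + 1])
                + "\t".join(str(st[n]) for n in names)
            )
        return "\n".join(out) + "\n"


def decode_state(
    record: SpikeRecord, nu_map: dict, t: float, tau: float = 0.015
) -> dict:
    """Decoded assignment at time ``t``: most recent spike within tau."""
    out = {}
    names = {n for (n, _) in nu_map}
    for name in names:
        out[name] = 0
    best: dict[str, tuple] = {}
    id_to_value = {nid: kv for kv, nid in nu_map.items()}
    for ts, nid in zip(record.times, record.neuron_ids):
        kv = id_to_value.get(int(nid))
        if kv is None:
            continue
        name, l = kv
        if ts <= t < ts + tau:
            prev = best.get(name)
            if prev is None or ts >= prev[0]:
                best[name] = (ts, l)
    for name, (_, l) in best.items():
        out[name] = l
    return out


def state_trace(
    record: SpikeRecord, nu_map: dict, t0: float, t1: float,
    tau: float = 0.015
) -> StateTrace:
    """Full decoded trajectory on [t0, t1] (later spikes win)."""
    id_to_value = {nid: kv for kv, nid in nu_map.items()}
    names = sorted({n for (n, _) in nu_map})
    # per variable: list of (time, value) change points
    changes: dict[str, list] = {n: [(t0, 0)] for n in names}
    per_var: dict[str, list] = {n: [] for n in names}
    for ts, nid in zip(record.times, record.neuron_ids):
        kv = id_to_value.get(int(nid))
        if kv is None:
            continue
        name, l = kv
        per_var[name].append((float(ts), l))
    for name in names:
        cps = changes[name]
        spikes = sorted(per_var[name])
        expiry = None
        for ts, l in spikes:
            if ts + tau <= t0 or ts >= t1:
                continue
            if expiry is not None and ts > expiry:
                cps.append((expiry, 0))
            cps.append((max(ts, t0), l))
            expiry = ts + tau
        if expiry is not None and expiry < t1:
            cps.append((expiry, 0))
    all_breaks = sorted(
        {t0, t1} | {t for cps in changes.values() for (t, _) in cps if t0 <= t <= t1}
    )
    # sweep
    states = []
    ptr = {n: 0 for n in names}
    cur = {n: 0 for n in names}
    for b in range(len(all_breaks) - 1):
        tb = all_breaks[b]
        for n in names:
            cps = changes[n]
            while ptr[n] < len(cps) and cps[ptr[n]][0] <= tb:
                cur[n] = cps[ptr[n]][1]
                ptr[n] += 1
        states.append(dict(cur))
    return StateTrace(np.array(all_breaks), states)


def state_histogram(trace: StateTrace, names=None):
    """Time-weighted dwell per fully non-zero decoded state.

    Returns ``(dwell dict, non-zero dwell total, zero_fraction)`` where
    zero_fraction is the dwell fraction of states with at least one 0.
    """
    names = names or list(trace.states[0])
    dwell: dict[tuple, float] = {}
    zero_time = 0.0
    total = 0.0
    durs = np.diff(trace.breaks)
    for st, d in zip(trace.states, durs):
        if d <= 0:
            continue
        total += d
        combo = tuple(st[n] for n in names)
        if 0 in combo:
            zero_time += d
        else:
            dwell[combo] = dwell.get(combo, 0.0) + d
    if not dwell:
        raise ValueError("no fully non-zero states in the window")
    nz = sum(dwell.values())
    return dwell, nz, zero_time / total


def dwell_to_table(dwell: dict, names, cards) -> DistributionTable:
    shape = tuple(cards[n] for n in names)
    p = np.zeros(shape)
    nz = sum(dwell.values())
    for combo, d in dwell.items():
        p[tuple(v - 1 for v in combo)] = d / nz
    return DistributionTable(
        [(n, list(range(1, cards[n] + 1))) for n in names], p
    )


# ----------------------------------------------------------------------
# sampling and inference runs
# ----------------------------------------------------------------------


def _random_state_pulses(index: CompositeIndex, gm, seed, amp=I_EXCITE,
                         width=0.002):
    """Current events initialising the network in a random state."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1417]))
    events = []
    on, off = [], []
    for var in gm.variables:
        v = int(rng.integers(1, var.cardinality + 1))
        nid = index.nu[(var.name, v)]
        on.append((nid, amp))
        off.append((nid, -amp))
    events.append((0.0, on))
    events.append((width, off))
    return events


def sample_stationary(
    sim: Simulator,
    index: CompositeIndex,
    gm: GraphicalModelSpec,
    duration: float = 300.0,
    burn_in: float = 20.0,
    seed: int = 0,
):
    """Run spontaneous activity and histogram the decoded states.

    Returns a dict with the empirical DistributionTable (zero-states
    excluded), the dwell fraction spent in zero-containing states, and
    the StateTrace.
    """
    if duration <= burn_in:
        raise ValueError("duration must exceed burn_in")
    sim.add_current_events(_random_state_pulses(index, gm, seed))
    sim.run_until(duration)
    record = sim.spike_record()
    nu_map = index.nu
    tau = next(iter(index.modules.values())).spec.params.tau
    trace = state_trace(record, nu_map, burn_in, duration, tau=tau)
    names = gm.names
    dwell, nz, zero_frac = state_histogram(trace, names)
    table = dwell_to_table(dwell, names, gm.card)
    return {
        "table": table,
        "zero_fraction": zero_frac,
        "trace": trace,
        "record": record,
    }


def infer_posterior(
    sim: Simulator,
    index: CompositeIndex,
    gm: GraphicalModelSpec,
    evidence: dict,
    duration: float = 0.4,
    seed: int = 0,
    burn_in: float = 0.0,
):
    """Clamp evidence and estimate posterior marginals of free variables.

    Evidence neurons are clamped with the same amplitudes as during
    training (+30 coding / -30 non-coding); no hidden-population gating
    is applied.  Marginals are estimated from time-weighted decoded
    states (zero dwell excluded) and, alongside, from output spike
    counts.
    """
    for k, v in evidence.items():
        if k not in gm.card:
            raise KeyError(f"unknown evidence variable {k}")
        if not 1 <= int(v) <= gm.card[k]:
            raise ValueError(f"evidence value {v} out of range for {k}")
    free = [n for n in gm.names if n not in evidence]
    if not free:
        return {"marginals": {}, "rate_marginals": {}, "record": None}
    deltas = []
    for k, v in evidence.items():
        for l in range(1, gm.card[k] + 1):
            amp = I_EXCITE if l == int(v) else I_INHIBIT
            deltas.append((index.nu[(k, l)], amp))
    sim.add_current_events([(0.0, deltas)])
    sim.add_current_events(
        _random_state_pulses(
            _SubsetIndex(index, free), _SubsetGM(gm, free), seed
        )
    )
    sim.run_until(duration)
    record = sim.spike_record()
    tau = next(iter(index.modules.values())).spec.params.tau
    free_map = {
        (n, l): nid for (n, l), nid in index.nu.items() if n in free
    }
    trace = state_trace(record, free_map, burn_in, duration, tau=tau)
    durs = np.diff(trace.breaks)
    marginals = {}
    for n in free:
        t_val = np.zeros(gm.card[n] + 1)
        for st, d in zip(trace.states, durs):
            t_val[st[n]] += d
        nz = t_val[1:].sum()
        marginals[n] = t_val[1:] / nz if nz > 0 else t_val[1:]
    rate_marginals = {}
    for n in free:
        counts = np.array(
            [
                len(record.for_neuron(index.nu[(n, l)]))
                for l in range(1, gm.card[n] + 1)
            ],
            dtype=float,
        )
        tot = counts.sum()
        rate_marginals[n] = counts / tot if tot > 0 else counts
    return {
        "marginals": marginals,
        "rate_marginals": rate_marginals,
        "record": record,
        "trace": trace,
    }


class _SubsetIndex:
    def __init__(self, index, names):
        self.nu = {
            (n, l): nid for (n, l), nid in index.nu.items() if n in names
        }


class _SubsetGM:
    def __init__(self, gm, names):
        self.variables = [v for v in gm.variables if v.name in names]


def estimate_rates(
    record: SpikeRecord,
    neuron_ids,
    kernel_tau: float = 0.1,
    t_grid=None,
    t_max: float = None,
):
    """Causal alpha-kernel smoothed instantaneous rates.

    The kernel ``K(t) = (t / tau^2) exp(-t / tau)`` for t > 0 integrates
    to one, so each spike contributes one unit of area to its neuron's
    trace.  Returns ``(t_grid, {neuron_id: rates})``.
    """
    if kernel_tau <= 0:
        raise ValueError("kernel_tau must be > 0")
    if t_grid is None:
        if t_max is None:
            t_max = float(record.times[-1]) if len(record) else 1.0
        t_grid = np.linspace(0.0, t_max, max(int(t_max / 0.002), 2))
    t_grid = np.asarray(t_grid, dtype=float)
    out = {}
    for nid in neuron_ids:
        ts = record.for_neuron(nid)
        r = np.zeros_like(t_grid)
        for s in ts:
            dt = t_grid - s
            mask = dt > 0
            r[mask] += dt[mask] / kernel_tau**2 * np.exp(-dt[mask] / kernel_tau)
        out[nid] = r
    return t_grid, out
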