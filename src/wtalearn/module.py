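"""The stochastic association module: construction, training, results.

The module is a three-layer motif (Fig.-2-style): input populations chi
(one neuron per value of each input variable), hidden winner-take-all
subpopulations alpha (one subpopulation per output value, lateral
inhibition through a shared pool of inhibitory neurons), and output
neurons zeta that relay the hidden subpopulations through strong fixed
synapses.  STDP on the chi->alpha synapses and intrinsic plasticity of
the alpha neurons let the module absorb the joint statistics of
presented (x, z) examples as a mixture-of-multinomials generative
model.

The public surface follows the Model/Results convention:
:class:`AssociationModule` describes the architecture and
:meth:`AssociationModule.fit` runs the training protocol and returns a
:class:`ModuleFitResults` carrying the parameter trajectory, analytic
diagnostics and a ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .genmodel import (
    DistributionTable,
    Theta,
    joint_marginal,
    kl_objective,
    theta_from_weights,
)
from .kernels import PSPKernel
from .network import CurrentSchedule, NetworkSpec, NeuronSpec, SynapseSpec
from .plasticity import PlasticityConfig, Schedule
from .simulator import Simulator

__all__ = [
    "VariableSpec",
    "ModuleParams",
    "ModuleSpec",
    "ModuleIndex",
    "default_b_minus",
    "build_module",
    "presentation_schedule",
    "train",
    "AssociationModule",
    "ModuleFitResults",
    "Checkpoint",
]

I_EXCITE = 30.0
I_INHIBIT = -30.0
I_GATE = -80.0
DT_EXAMPLE = 0.1


@dataclass(frozen=True)
class VariableSpec:
    """A discrete variable with values 1..cardinality (0 = no spike)."""

    name: str
    cardinality: int

    def __post_init__(self):
        if self.cardinality < 2:
            raise ValueError("cardinality must be >= 2")


@dataclass
class ModuleParams:
    """Wiring constants and initial-value distributions of one module."""

    w_pp: float = 20.0  # alpha -> zeta relay weight
    w_e2i: float = 80.0  # alpha -> inhibitory pool
    w_i2e: float = -7.0  # inhibitory pool -> alpha
    b_inh: float = -10.0
    b_pp: float = -10.0
    n_inhibitory: int = 5
    tau: float = 0.015
    epsp: PSPKernel = field(
        default_factory=lambda: PSPKernel(kind="alpha")
    )
    w_init_mean: float = 4.0 / 3.0
    w_init_sd: float = 0.1
    b_init_mean: float = 5.0
    b_init_sd: float = 0.1

    @property
    def ipsp(self) -> PSPKernel:
        # rectangular IPSPs approximate fast-spiking inhibition even
        # when excitatory synapses carry alpha-shaped EPSPs
        return PSPKernel(kind="rectangular", tau=self.tau)


def default_b_minus(cardinalities, T: float) -> float:
    """Bias offset counter-balancing a module's average total input.

    ``2.5 * T * (-|B| ln 0.2 - sum_i ln(M_i + 1) + ln 0.02)`` for a
    module with input cardinalities ``M_i``; larger input sets push the
    offset more negative so the intrinsic rule stabilises comparable
    bias ranges in every module.
    """
    B = len(list(cardinalities))
    s = sum(math.log(m + 1) for m in cardinalities)
    return 2.5 * T * (-B * math.log(0.2) - s + math.log(0.02))


@dataclass
class ModuleSpec:
    """Complete description of one association module."""

    inputs: list
    output: VariableSpec
    hidden: tuple  # J^l per output value
    params: ModuleParams = field(default_factory=ModuleParams)
    plasticity: PlasticityConfig = None

    def __post_init__(self):
        self.inputs = [
            v if isinstance(v, VariableSpec) else VariableSpec(*v)
            for v in self.inputs
        ]
        if not isinstance(self.output, VariableSpec):
            self.output = VariableSpec(*self.output)
        if isinstance(self.hidden, int):
            self.hidden = tuple(
                self.hidden for _ in range(self.output.cardinality)
            )
        self.hidden = tuple(int(j) for j in self.hidden)
        if len(self.hidden) != self.output.cardinality:
            raise ValueError("need one hidden count per output value")
        if any(j < 1 for j in self.hidden):
            raise ValueError("hidden counts must be >= 1")
        if self.plasticity is None:
            T = 1.0
            self.plasticity = PlasticityConfig(
                T=T,
                b_minus=default_b_minus(
                    [v.cardinality for v in self.inputs], T
                ),
                tau=self.params.tau,
            )

    @property
    def M(self):
        return tuple(v.cardinality for v in self.inputs)

    @property
    def L(self):
        return self.output.cardinality

    @property
    def n_components(self):
        return sum(self.hidden)


class ModuleIndex:
    """Neuron-id bookkeeping for one module inside a NetworkSpec.

    ``chi[(i, m)]`` (1-based value m), ``alpha[(l, j)]``, ``zeta[l]``
    map roles to neuron ids; ``syn[(i, m, c)]`` maps a plastic synapse
    (input i, value m, hidden component c) to its synapse index.
    """

    def __init__(self, spec: ModuleSpec):
        self.spec = spec
        self.chi = {}
        self.alpha = {}
        self.zeta = {}
        self.inhibitory = []
        self.syn = {}
        self.comp = []  # component order: (l, j)
        for l, jl in enumerate(spec.hidden, start=1):
            for j in range(1, jl + 1):
                self.comp.append((l, j))

    @property
    def alpha_ids(self):
        return [self.alpha[lj] for lj in self.comp]

    def alpha_of(self, l: int):
        return [self.alpha[(l2, j)] for (l2, j) in self.comp if l2 == l]

    def legend_rows(self):
        rows = []
        for (i, m), nid in sorted(self.chi.items()):
            rows.append((nid, f"chi[{self.spec.inputs[i].name}={m}]"))
        for (l, j), nid in sorted(self.alpha.items()):
            rows.append((nid, f"alpha[{self.spec.output.name}={l}][j={j}]"))
        for l, nid in sorted(self.zeta.items()):
            rows.append((nid, f"zeta[{self.spec.output.name}={l}]"))
        for k, nid in enumerate(self.inhibitory):
            rows.append((nid, f"inh[{k}]"))
        return sorted(rows)

    def legend_dumps(self) -> str:
        out = ["# neuron_id\trole"]
        out += ["%d\t%s" % r for r in self.legend_rows()]
        return "\n".join(out) + "\n"

    # -- parameter extraction -------------------------------------------

    def weight_arrays(self, sim_or_values):
        """Plastic weights as per-input arrays of shape (M_i, C)."""
        values = (
            sim_or_values.weights()
            if hasattr(sim_or_values, "weights")
            else np.asarray(sim_or_values)
        )
        C = len(self.comp)
        out = []
        for i, var in enumerate(self.spec.inputs):
            arr = np.empty((var.cardinality, C))
            for m in range(1, var.cardinality + 1):
                for c in range(C):
                    arr[m - 1, c] = values[self.syn[(i, m, c)]]
            out.append(arr)
        return out

    def bias_array(self, sim_or_values):
        values = (
            sim_or_values.biases()
            if hasattr(sim_or_values, "biases")
            else np.asarray(sim_or_values)
        )
        return np.array([values[self.alpha[lj]] for lj in self.comp])

    def theta(self, weights, biases, V: float = 50.0) -> Theta:
        spec = self.spec
        return theta_from_weights(
            weights,
            biases,
            spec.plasticity,
            M=spec.M,
            J=spec.hidden,
            V=V,
            input_names=tuple(v.name for v in spec.inputs),
            output_name=spec.output.name,
        )


def _redraw_in_bounds(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise RuntimeError("could not draw an in-bounds initial value")


def build_module(
    spec: ModuleSpec,
    seed: int = 0,
    net: NetworkSpec | None = None,
    index: ModuleIndex | None = None,
    input_neuron_ids: dict | None = None,
    output_neuron_ids: dict | None = None,
):
    """Instantiate a module as neurons and synapses in a NetworkSpec.

    When ``input_neuron_ids`` maps ``(i, m)`` to existing neuron ids
    (composite networks alias another module's output population as
    input), no chi neurons are created for those entries; likewise
    ``output_neuron_ids`` (value -> id) aliases the output population.
    Returns ``(net, index)``.
    """
    p = spec.params
    cfg = spec.plasticity
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    net = net if net is not None else NetworkSpec()
    index = index if index is not None else ModuleIndex(spec)

    for i, var in enumerate(spec.inputs):
        for m in range(1, var.cardinality + 1):
            if input_neuron_ids and (i, m) in input_neuron_ids:
                index.chi[(i, m)] = input_neuron_ids[(i, m)]
            else:
                index.chi[(i, m)] = net.add_neuron(
                    NeuronSpec(
                        bias=p.b_pp,
                        refractory=p.tau,
                        name=f"chi[{var.name}={m}]",
                    )
                )
    for l, jl in enumerate(spec.hidden, start=1):
        for j in range(1, jl + 1):
            b0 = _redraw_in_bounds(
                rng, p.b_init_mean, p.b_init_sd, cfg.b_min, cfg.b_max
            )
            index.alpha[(l, j)] = net.add_neuron(
                NeuronSpec(
                    bias=b0,
                    refractory=p.tau,
                    plastic_bias=True,
                    name=f"alpha[{spec.output.name}={l}][j={j}]",
                )
            )
    for l in range(1, spec.L + 1):
        if output_neuron_ids and l in output_neuron_ids:
            index.zeta[l] = output_neuron_ids[l]
        else:
            index.zeta[l] = net.add_neuron(
                NeuronSpec(
                    bias=p.b_pp,
                    refractory=p.tau,
                    name=f"zeta[{spec.output.name}={l}]",
                )
            )
    for k in range(p.n_inhibitory):
        index.inhibitory.append(
            net.add_neuron(
                NeuronSpec(
                    bias=p.b_inh,
                    refractory=p.tau,
                    is_inhibitory=True,
                    name=f"inh[{k}]",
                )
            )
        )

    # plastic chi -> alpha, all-to-all, Gaussian init redrawn into bounds
    for c, (l, j) in enumerate(index.comp):
        post = index.alpha[(l, j)]
        for i, var in enumerate(spec.inputs):
            for m in range(1, var.cardinality + 1):
                w0 = _redraw_in_bounds(
                    rng, p.w_init_mean, p.w_init_sd, cfg.w_min, cfg.w_max
                )
                sidx = net.add_synapse(
                    SynapseSpec(
                        pre=index.chi[(i, m)],
                        post=post,
                        weight=w0,
                        kernel=p.epsp,
                        plastic=True,
                    )
                )
                index.syn[(i, m, c)] = sidx
    # fixed alpha -> zeta relays
    for l, j in index.comp:
        net.add_synapse(
            SynapseSpec(
                pre=index.alpha[(l, j)],
                post=index.zeta[l],
                weight=p.w_pp,
                kernel=p.epsp,
            )
        )
    # lateral inhibition: every alpha -> each inhibitory, and back
    for l, j in index.comp:
        a = index.alpha[(l, j)]
        for inh in index.inhibitory:
            net.add_synapse(
                SynapseSpec(pre=a, post=inh, weight=p.w_e2i, kernel=p.ipsp)
            )
            net.add_synapse(
                SynapseSpec(pre=inh, post=a, weight=p.w_i2e, kernel=p.ipsp)
            )
    return net, index


def presentation_schedule(
    index: ModuleIndex,
    example: dict,
    t0: float,
    dt_example: float = DT_EXAMPLE,
    clamp_output: bool = False,
) -> CurrentSchedule:
    """Currents presenting one example for ``[t0, t0 + dt_example)``.

    Coding input neurons receive +30, non-coding ones -30; hidden
    neurons outside the subpopulation of the example's output value are
    gated with -80.  With ``clamp_output`` the output population is
    clamped like the inputs (used in composite networks, where outputs
    are other modules' inputs).
    """
    spec = index.spec
    t1 = t0 + dt_example
    sched = CurrentSchedule()
    for i, var in enumerate(spec.inputs):
        v = int(example[var.name])
        if not 1 <= v <= var.cardinality:
            raise ValueError(
                f"value {v} out of range for {var.name}"
            )
        for m in range(1, var.cardinality + 1):
            sched.add(
                index.chi[(i, m)],
                I_EXCITE if m == v else I_INHIBIT,
                t0,
                t1,
            )
    zv = int(example[spec.output.name])
    if not 1 <= zv <= spec.L:
        raise ValueError(f"value {zv} out of range for {spec.output.name}")
    for (l, j), nid in index.alpha.items():
        if l != zv:
            sched.add(nid, I_GATE, t0, t1)
    if clamp_output:
        for l, nid in index.zeta.items():
            sched.add(nid, I_EXCITE if l == zv else I_INHIBIT, t0, t1)
    return sched


@dataclass
class Checkpoint:
    t: float
    weights: list  # per input, (M_i, C)
    biases: np.ndarray  # (C,)


def train(
    spec: ModuleSpec,
    examples,
    total_duration: float,
    seed: int = 0,
    checkpoint_every: float = 60.0,
    dt_example: float = DT_EXAMPLE,
    record: bool = False,
):
    """Train one module on a stream of examples; return the trajectory.

    ``examples`` is a sequence of assignments (dicts); one example is
    presented per ``dt_example`` slot, back to back.  Returns
    ``(trajectory, index, sim)`` where the trajectory is a list of
    :class:`Checkpoint` at t = 0, checkpoint_every, ...
    """
    net, index = build_module(spec, seed=seed)
    sim = Simulator(
        net,
        seed=np.random.SeedSequence([int(seed), 0xD11E]).generate_state(1)[0],
        plasticity=spec.plasticity,
        record=record,
    )
    n_slots = int(round(total_duration / dt_example))
    examples = list(examples)
    if len(examples) < n_slots:
        raise ValueError(
            f"need {n_slots} examples for {total_duration} s, "
            f"got {len(examples)}"
        )
    trajectory = [
        Checkpoint(0.0, index.weight_arrays(sim), index.bias_array(sim))
    ]
    n_check = int(round(total_duration / checkpoint_every))
    slots_per_check = int(round(checkpoint_every / dt_example))
    slot = 0
    for k in range(n_check):
        events = []
        for s in range(slots_per_check):
            t0 = (slot + s) * dt_example
            sched = presentation_schedule(
                index, examples[slot + s], t0, dt_example
            )
            events.extend(Simulator.events_from_schedule(sched))
        sim.add_current_events(events)
        slot += slots_per_check
        sim.run_until(slot * dt_example)
        sim.commit_biases()
        trajectory.append(
            Checkpoint(
                slot * dt_example,
                index.weight_arrays(sim),
                index.bias_array(sim),
            )
        )
    return trajectory, index, sim


class AssociationModule:
    """Model object for one stochastic association module.

    Parameters
    ----------
    inputs : list of (name, cardinality) or VariableSpec
    output : (name, cardinality) or VariableSpec
    hidden : int or tuple
        Hidden neurons per output value.
    params : ModuleParams, optional
    plasticity : PlasticityConfig, optional
        Defaults to T=1 with the structure-derived bias offset.

    Examples
    --------
    >>> mod = AssociationModule([("x1", 2), ("x2", 2)], ("z", 2), hidden=2)
    >>> res = mod.fit(target, duration=1200.0, seed=1)   # doctest: +SKIP
    >>> res.summary()                                    # doctest: +SKIP
    """

    def __init__(self, inputs, output, hidden=2, params=None, plasticity=None):
        self.spec = ModuleSpec(
            inputs=list(inputs),
            output=output,
            hidden=hidden,
            params=params or ModuleParams(),
            plasticity=plasticity,
        )

    def build(self, seed: int = 0):
        return build_module(self.spec, seed=seed)

    def fit(
        self,
        target: DistributionTable = None,
        examples=None,
        duration: float = 1200.0,
        seed: int = 0,
        checkpoint_every: float = 60.0,
        dt_example: float = DT_EXAMPLE,
    ) -> "ModuleFitResults":
        """Train on examples drawn from ``target`` (or a given stream)."""
        from .experiments import sample_examples

        n_slots = int(round(duration / dt_example))
        if examples is None:
            if target is None:
                raise ValueError("need a target table or an example stream")
            examples = sample_examples(
                target,
                n_slots,
                seed=np.random.SeedSequence(
                    [int(seed), 0xE85]
                ).generate_state(1)[0],
            )
        trajectory, index, sim = train(
            self.spec,
            examples,
            duration,
            seed=seed,
            checkpoint_every=checkpoint_every,
            dt_example=dt_example,
        )
        return ModuleFitResults(
            model=self,
            trajectory=trajectory,
            index=index,
            target=target,
            seed=seed,
        )


class ModuleFitResults:
    """Trained-module results: parameter trajectory plus diagnostics."""

    def __init__(self, model, trajectory, index, target=None, seed=None):
        self.model = model
        self.trajectory = trajectory
        self.index = index
        self.target = target
        self.seed = seed

    @property
    def spec(self) -> ModuleSpec:
        return self.model.spec

    def theta_at(self, k: int) -> Theta:
        cp = self.trajectory[k]
        return self.index.theta(cp.weights, cp.biases)

    @property
    def theta(self) -> Theta:
        return self.theta_at(len(self.trajectory) - 1)

    @property
    def checkpoint_times(self):
        return [cp.t for cp in self.trajectory]

    def fitted_joint(self) -> DistributionTable:
        return joint_marginal(self.theta)

    def kl_curve(self, target: DistributionTable = None) -> np.ndarray:
        """Analytic KL(p* || p(.; theta_t)) at every checkpoint."""
        target = target if target is not None else self.target
        if target is None:
            raise ValueError("no target distribution available")
        return np.array(
            [
                kl_objective(self.theta_at(k), target)["U"]
                for k in range(len(self.trajectory))
            ]
        )

    def frozen_simulator(self, seed: int = 0, record=True) -> Simulator:
        """A simulator of the trained module with plasticity off."""
        net, index = build_module(self.spec, seed=0)
        sim = Simulator(net, seed=seed, record=record)
        values = sim.weights()
        final = self.trajectory[-1]
        for i, var in enumerate(self.spec.inputs):
            for m in range(1, var.cardinality + 1):
                for c in range(len(index.comp)):
                    values[index.syn[(i, m, c)]] = final.weights[i][m - 1, c]
        sim.set_weights(values)
        biases = sim.biases()
        for c, lj in enumerate(index.comp):
            biases[index.alpha[lj]] = final.biases[c]
        sim.set_biases(biases)
        self._frozen_index = index
        return sim

    def plot_kl(self, ax=None, target=None):
        """Plot the analytic KL objective over the checkpoints."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.checkpoint_times, self.kl_curve(target), marker="o")
        ax.set_xlabel("training time [s]")
        ax.set_ylabel("KL(p* || p(theta)) [nats]")
        return ax

    def plot_joint(self, ax=None):
        """Bar comparison of the learned joint against the target."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels, model, target = [], [], []
        tab = self.fitted_joint()
        for assignment, p in tab.assignments():
            if 0 in assignment.values():
                continue
            labels.append(
                "".join(str(assignment[n]) for n in tab.names)
            )
            model.append(p)
            target.append(
                self.target.prob(assignment) if self.target else float("nan")
            )
        xs = np.arange(len(labels))
        ax.bar(xs - 0.2, target, width=0.4, label="target", color="0.3")
        ax.bar(xs + 0.2, model, width=0.4, label="model")
        ax.set_xticks(xs, labels, rotation=90)
        ax.legend()
        return ax

    def summary(self) -> str:
        spec = self.spec
        lines = []
        lines.append("Association module fit")
        lines.append("=" * 58)
        lines.append(
            "inputs: "
            + ", ".join(f"{v.name}(1..{v.cardinality})" for v in spec.inputs)
        )
        lines.append(
            f"output: {spec.output.name}(1..{spec.output.cardinality})"
            f"   hidden per value: {spec.hidden}"
        )
        lines.append(
            f"T={spec.plasticity.T}  w-={spec.plasticity.w_minus:.4f}  "
            f"b-={spec.plasticity.b_minus:.4f}"
        )
        lines.append(
            f"trained {self.trajectory[-1].t:.0f} s, "
            f"{len(self.trajectory)} checkpoints, seed={self.seed}"
        )
        from .genmodel import normalization_residuals

        c0, _, mx = normalization_residuals(self.theta)
        lines.append(f"normalization residuals: c0={c0:+.4f}  max|c|={mx:.4f}")
        if self.target is not None:
            kl = self.kl_curve()
            lines.append(
                f"KL(p*||p(theta)): initial {kl[0]:.4f} -> final "
                f"{kl[-1]:.4f} nats"
            )
        lines.append("-" * 58)
        lines.append("final model joint (non-zero assignments):")
        tab = self.fitted_joint()
        for assignment, p in tab.assignments():
            if 0 in assignment.values():
                continue
            key = ", ".join(f"{k}={v}" for k, v in assignment.items())
            tgt = ""
            if self.target is not None:
                try:
                    tgt = f"   target {self.target.prob(assignment):.3f}"
                except (KeyError, ValueError):
                    tgt = ""
            lines.append(f"  p({key}) = {p:.3f}{tgt}")
        return "\n".join(lines)
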