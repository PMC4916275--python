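"""Study fixtures and the evaluation battery.

Two reference problems exercise the whole stack:

* **Example 1** — a single association module with two binary inputs
  and a binary output learns a joint p*(x1, x2, z) whose per-output
  input distributions are multimodal (an XOR-like structure for z = 2),
  so each hidden subpopulation must split into two specialised mixture
  components.
* **Example 2** — a four-variable "explaining away" Bayesian network
  from visual perception (relative reflectance y1 and 3D shape y2 are
  competing causes of the observed shading y3; the contour y4 depends
  on the shape).  Four recursively interconnected modules learn the
  blanket marginals simultaneously, after which the network answers
  posterior queries by sampling.

The fixture constants below are immutable study conditions: the coding
window tau = 15 ms, wiring weights (relay 20, excitation of the
inhibitory pool 80, inhibition -7, biases -10), alpha-EPSP shape
(eps0 = 2.8, tau_alpha = 8.5 ms), clip bounds, Gaussian initialisation
(weights mean w_max/3 or 3.0, SD 0.1; biases mean 5, SD 0.1),
potentiation scaling (T = 0.4 / 0.58), the learning-rate schedules
(eta linear 0.002 -> 0.0006 over the first 600 s then 0; eta' 0.01
then 0.02), 100 ms example presentations, and 1200 s of training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .composite import CompositeNetwork, GraphicalModelSpec
from .genmodel import DistributionTable
from .kernels import PSPKernel
from .module import (
    AssociationModule,
    ModuleParams,
    default_b_minus,
)
from .plasticity import PlasticityConfig, Schedule

__all__ = [
    "FixtureConfig",
    "target_example1",
    "target_example2",
    "example1_module",
    "example2_network",
    "sample_examples",
    "evaluate_run",
    "training_schedules",
]

TAU = 0.015
DT_EXAMPLE = 0.1
TRAIN_DURATION = 1200.0
CHECKPOINT_EVERY = 60.0
W_MINUS = 2.5 * math.log(0.2)

EX1 = dict(T=0.4, w_max=5.0, w_init_mean=3.0)
EX2 = dict(
    T=0.58,
    w_max={"y1": 4.0, "y2": 4.0, "y3": 4.0, "y4": 2.0},
)
B_BOUNDS = (-30.0, 5.0)


def training_schedules():
    """The printed learning-rate schedules for both examples.

    Synaptic rate: linear 0.002 -> 0.0006 over [0, 600] s, then 0.
    Bias rate: 0.01 on [0, 600) s, then 0.02.
    """
    eta = Schedule([(0.0, 0.002), (600.0, 0.0006), (600.0, 0.0)])
    eta_b = Schedule([(0.0, 0.01), (600.0, 0.01), (600.0, 0.02)])
    return eta, eta_b


def target_example1() -> DistributionTable:
    """The 8-entry target joint p*(x1, x2, z) of Example 1."""
    p = np.zeros((2, 2, 2))  # axes: x1, x2, z (values 1..2)
    p[0, 0, 0] = 0.04
    p[0, 1, 0] = 0.21
    p[1, 0, 0] = 0.04
    p[1, 1, 0] = 0.21
    p[0, 0, 1] = 0.04
    p[0, 1, 1] = 0.21
    p[1, 0, 1] = 0.21
    p[1, 1, 1] = 0.04
    return DistributionTable(
        [("x1", [1, 2]), ("x2", [1, 2]), ("z", [1, 2])], p
    )


def target_example2() -> GraphicalModelSpec:
    """The explaining-away Bayesian network (priors 0.5, printed CPTs).

    p(y1) p(y2) p(y3 | y1, y2) p(y4 | y2) over four binary variables;
    the module input set of y3 is {y1, y2, y4}.
    """
    # cpt[y1-1, y2-1, y3-1] etc.; columns are the variable's own values
    cpt_y3 = np.zeros((2, 2, 2))
    cpt_y3[0, 0, 1] = 0.13  # p(y3=2 | y1=1, y2=1)
    cpt_y3[0, 1, 1] = 0.87
    cpt_y3[1, 0, 1] = 0.87
    cpt_y3[1, 1, 1] = 0.13
    cpt_y3[..., 0] = 1.0 - cpt_y3[..., 1]
    cpt_y4 = np.zeros((2, 2))
    cpt_y4[0, 1] = 0.13  # p(y4=2 | y2=1)
    cpt_y4[1, 1] = 0.87
    cpt_y4[:, 0] = 1.0 - cpt_y4[:, 1]
    prior = np.array([0.5, 0.5])
    return GraphicalModelSpec(
        variables=[("y1", 2), ("y2", 2), ("y3", 2), ("y4", 2)],
        parents={"y1": [], "y2": [], "y3": ["y1", "y2"], "y4": ["y2"]},
        cpts={"y1": prior, "y2": prior, "y3": cpt_y3, "y4": cpt_y4},
        input_sets={"y3": ["y1", "y2", "y4"]},
    )


def _plasticity(T: float, w_max: float, n_inputs_cards) -> PlasticityConfig:
    eta, eta_b = training_schedules()
    return PlasticityConfig(
        eta=eta,
        eta_b=eta_b,
        w_minus=W_MINUS,
        b_minus=default_b_minus(n_inputs_cards, T),
        T=T,
        tau=TAU,
        w_min=0.0,
        w_max=w_max,
        b_min=B_BOUNDS[0],
        b_max=B_BOUNDS[1],
    )


def example1_module(hidden: int = 2, kernel: str = "alpha") -> AssociationModule:
    """The Example-1 learning module with every printed parameter."""
    params = ModuleParams(
        tau=TAU,
        epsp=PSPKernel(kind=kernel, tau=TAU),
        w_init_mean=EX1["w_init_mean"],
        w_init_sd=0.1,
        b_init_mean=5.0,
        b_init_sd=0.1,
    )
    plasticity = _plasticity(EX1["T"], EX1["w_max"], [2, 2])
    return AssociationModule(
        inputs=[("x1", 2), ("x2", 2)],
        output=("z", 2),
        hidden=hidden,
        params=params,
        plasticity=plasticity,
    )


def example2_network(hidden: int = 2, kernel: str = "alpha") -> CompositeNetwork:
    """The four-module Example-2 network with every printed parameter."""
    gm = target_example2()
    params = {}
    plasticity = {}
    for var in gm.variables:
        w_max = EX2["w_max"][var.name]
        params[var.name] = ModuleParams(
            tau=TAU,
            epsp=PSPKernel(kind=kernel, tau=TAU),
            w_init_mean=w_max / 3.0,
            w_init_sd=0.1,
            b_init_mean=5.0,
            b_init_sd=0.1,
        )
        cards = [gm.card[n] for n in gm.module_inputs(var.name)]
        plasticity[var.name] = _plasticity(EX2["T"], w_max, cards)
    return CompositeNetwork(
        gm, hidden=hidden, params=params, plasticity=plasticity
    )


@dataclass
class FixtureConfig:
    """Everything needed to reproduce one study run."""

    name: str
    duration: float = TRAIN_DURATION
    dt_example: float = DT_EXAMPLE
    checkpoint_every: float = CHECKPOINT_EVERY
    hidden: int = 2
    kernel: str = "alpha"

    def build(self):
        if self.name == "example1":
            return example1_module(hidden=self.hidden, kernel=self.kernel)
        if self.name == "example2":
            return example2_network(hidden=self.hidden, kernel=self.kernel)
        raise KeyError(f"unknown fixture {self.name!r}")

    def target(self):
        if self.name == "example1":
            return target_example1()
        return target_example2().joint()


def sample_examples(dist: DistributionTable, n: int, seed: int = 0) -> list:
    """Draw ``n`` i.i.d. assignments from a probability table."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(int(seed))
    flat = dist.probs.ravel()
    flat = flat / flat.sum()
    draws = rng.choice(len(flat), size=n, p=flat)
    combos = np.array(
        np.unravel_index(draws, dist.probs.shape)
    ).T  # (n, n_vars) of value indices
    names = dist.names
    values = [v for _, v in dist.variables]
    return [
        {names[i]: values[i][ci] for i, ci in enumerate(combo)}
        for combo in combos
    ]


def evaluate_run(results, target: DistributionTable = None,
                 sampled_kl_checkpoints=None, sample_duration: float = 300.0):
    """Evaluation battery for a fit: KL curves and table comparisons.

    For a module fit: the analytic KL(p* || p(theta_t)) curve and the
    final joint table versus the target.  For a network fit: per-module
    KL curves and their sum, computed analytically from theta, never by
    simulation; optionally (``sampled_kl_checkpoints``) the
    network-level KL estimated from finite stationary-sampling runs at
    the given checkpoints, with the sampling-error scale reported.
    """
    from .module import ModuleFitResults

    report = {}
    if isinstance(results, ModuleFitResults):
        tgt = target if target is not None else results.target
        report["kind"] = "module"
        report["checkpoint_times"] = results.checkpoint_times
        report["kl_curve"] = results.kl_curve(tgt)
        report["final_joint"] = results.fitted_joint()
        report["target"] = tgt
        model_nz = _nonzero_table(report["final_joint"], tgt)
        report["total_variation"] = tgt.total_variation(model_nz)
    else:
        report["kind"] = "network"
        report["checkpoint_times"] = results.checkpoint_times
        report["module_kl_curves"] = results.module_kl_curves()
        report["network_objective_curve"] = results.network_objective_curve()
        if sampled_kl_checkpoints is not None:
            report["sampled_network_kl"] = results.sampled_network_kl(
                checkpoints=sampled_kl_checkpoints,
                duration=sample_duration,
            )
    return report


def _nonzero_table(model_table, target):
    """Model joint restricted to the target's (non-zero) domain."""
    names = target.names
    t = model_table.marginal(names)
    idx = []
    for n, vals in t.variables:
        tvals = target.variables[target.names.index(n)][1]
        idx.append([vals.index(v) for v in tvals])
    p = t.probs
    for ax, sel in enumerate(idx):
        p = np.take(p, sel, axis=ax)
    return DistributionTable(
        target.variables, p / 1.0, normalized=False
    )
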