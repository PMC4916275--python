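"""STDP and intrinsic-plasticity rules.

The synaptic rule is applied at each spike of a plastic (hidden-layer)
neuron: every afferent plastic synapse is potentiated by
``exp(-T*(w + w_minus)) - 1`` if its presynaptic neuron fired within the
preceding coincidence window of length ``tau`` (pre-before-post, the
causal branch), and depressed by a constant ``-1`` otherwise.  The
neuron's excitability (bias) grows at its own spikes by
``tau * exp(-T*(b + b_minus))`` and decays between spikes at the
constant rate ``eta_b`` (the bias learning rate), so that excitability
tracks the neuron's long-run share of activity.

``T`` is a potentiation scaling factor (1 in the analytic treatment;
the example fixtures use 0.4 and 0.58).  Learning rates may follow
piecewise-linear schedules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Schedule",
    "PlasticityConfig",
    "stdp_delta",
    "intrinsic_delta",
    "bias_decay",
    "on_post_spike",
]


class Schedule:
    """Piecewise-linear, possibly discontinuous map from time to a rate.

    Built from breakpoints ``[(t0, r0), (t1, r1), ...]``; the rate is
    linearly interpolated between consecutive breakpoints and held
    constant after the last one.  A jump is expressed by repeating a
    time with two rates.  Rates must be non-negative.
    """

    def __init__(self, breakpoints):
        if isinstance(breakpoints, (int, float)):
            breakpoints = [(0.0, float(breakpoints))]
        pts = [(float(t), float(r)) for t, r in breakpoints]
        if not pts:
            raise ValueError("schedule needs at least one breakpoint")
        if any(r < 0 for _, r in pts):
            raise ValueError("schedule rates must be non-negative")
        if any(pts[i + 1][0] < pts[i][0] for i in range(len(pts) - 1)):
            raise ValueError("schedule breakpoints must be time-ordered")
        self.points = pts

    @classmethod
    def constant(cls, rate: float) -> "Schedule":
        return cls([(0.0, rate)])

    def __call__(self, t: float) -> float:
        pts = self.points
        if t <= pts[0][0]:
            return pts[0][1]
        for (t0, r0), (t1, r1) in zip(pts, pts[1:]):
            if t0 <= t < t1:
                if t1 == t0:
                    continue
                return r0 + (r1 - r0) * (t - t0) / (t1 - t0)
        return pts[-1][1]

    def integral(self, t0: float, t1: float) -> float:
        """Exact integral of the rate over ``[t0, t1]``."""
        if t1 < t0:
            raise ValueError("integral needs t0 <= t1")
        # integrate trapezoid segments clipped to [t0, t1]
        total = 0.0
        pts = self.points
        grid = [p[0] for p in pts]
        # leading constant piece
        if t0 < grid[0]:
            total += (min(t1, grid[0]) - t0) * pts[0][1]
        for (ta, ra), (tb, rb) in zip(pts, pts[1:]):
            lo, hi = max(t0, ta), min(t1, tb)
            if hi <= lo or tb == ta:
                continue
            slope = (rb - ra) / (tb - ta)
            r_lo = ra + slope * (lo - ta)
            r_hi = ra + slope * (hi - ta)
            total += 0.5 * (r_lo + r_hi) * (hi - lo)
        if t1 > grid[-1]:
            total += (t1 - max(t0, grid[-1])) * pts[-1][1]
        return total


@dataclass
class PlasticityConfig:
    """All tunables of the learning rules for one module.

    ``w_minus``/``b_minus`` are the baseline offsets relating synaptic
    weights and biases to the generative-model parameters; ``T`` scales
    the potentiation branch; clip bounds confine the trajectories.
    """

    eta: Schedule = field(default_factory=lambda: Schedule.constant(0.002))
    eta_b: Schedule = field(default_factory=lambda: Schedule.constant(0.01))
    w_minus: float = 2.5 * math.log(0.2)
    b_minus: float = -5.0
    T: float = 1.0
    tau: float = 0.015
    w_min: float = 0.0
    w_max: float = 5.0
    b_min: float = -30.0
    b_max: float = 5.0

    def __post_init__(self) -> None:
        if not isinstance(self.eta, Schedule):
            self.eta = Schedule(self.eta)
        if not isinstance(self.eta_b, Schedule):
            self.eta_b = Schedule(self.eta_b)
        if self.w_min > self.w_max or self.b_min > self.b_max:
            raise ValueError("clip bounds must be ordered")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


def stdp_delta(w: float, pre_active: bool, cfg: PlasticityConfig) -> float:
    """Raw STDP weight change (before the learning rate is applied)."""
    if pre_active:
        return math.exp(-cfg.T * (w + cfg.w_minus)) - 1.0
    return -1.0


def intrinsic_delta(b: float, cfg: PlasticityConfig) -> float:
    """Raw spike-triggered bias change (before the learning rate)."""
    return cfg.tau * math.exp(-cfg.T * (b + cfg.b_minus))


def bias_decay(b: float, dt: float, cfg: PlasticityConfig, t0: float = 0.0) -> float:
    """Continuous bias decay accrued over ``[t0, t0+dt]``, floored at b_min.

    The decay rate is the (possibly scheduled) bias learning rate, so
    the lazily accumulated result is identical to continuous decay.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return max(cfg.b_min, b - cfg.eta_b.integral(t0, t0 + dt))


def on_post_spike(weights, pre_active, bias, t, last_bias_time, cfg):
    """Apply one post-spike plasticity step to a hidden neuron.

    Parameters
    ----------
    weights : sequence of float
        Current afferent plastic weights.
    pre_active : sequence of bool
        Whether each presynaptic partner fired within ``[t - tau, t]``.
    bias, last_bias_time : float
        Bias value and the time up to which its decay has been applied.
    t : float
        Spike time; learning rates are evaluated here.

    Returns ``(new_weights, new_bias)``, all clipped to the configured
    bounds.
    """
    eta = cfg.eta(t)
    new_w = [
        min(cfg.w_max, max(cfg.w_min, w + eta * stdp_delta(w, act, cfg)))
        for w, act in zip(weights, pre_active)
    ]
    b = bias_decay(bias, t - last_bias_time, cfg, t0=last_bias_time)
    b = min(cfg.b_max, max(cfg.b_min, b + cfg.eta_b(t) * intrinsic_delta(b, cfg)))
    return new_w, b
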