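"""Postsynaptic-potential kernels.

Two kernel shapes are supported:

* a rectangular kernel of value 1 on the half-open window ``[0, tau)`` —
  the theoretically tractable shape whose duration equals the refractory
  period / coding window ``tau``;
* an alpha-shaped EPSP, a scaled and shifted version of the canonical
  ``e * t * exp(-t)`` hump, truncated where the base kernel crosses its
  half height, so that the kernel is continuous and compactly supported.

On repeated presynaptic spikes a synapse's trace is *replaced* by the
kernel of the most recent spike; overlapping PSPs from the same synapse
are never summed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = ["PSPKernel", "rect_psp", "alpha_psp", "alpha_half_height_roots"]


def alpha_half_height_roots() -> tuple[float, float]:
    """Roots ``t1 < 1 < t2`` of ``e * t * exp(-t) = 1/2``.

    The base alpha kernel ``e*t*exp(-t)`` peaks at 1 for t=1; the two
    half-height abscissae delimit the support of the truncated EPSP.
    """
    f = lambda t: math.e * t * math.exp(-t) - 0.5
    t1 = brentq(f, 1e-9, 1.0, xtol=1e-15)
    t2 = brentq(f, 1.0, 10.0, xtol=1e-15)
    return t1, t2


_T1, _T2 = alpha_half_height_roots()


@dataclass(frozen=True)
class PSPKernel:
    """Shape parameters of one postsynaptic-potential kernel.

    Parameters
    ----------
    kind : {"rectangular", "alpha"}
    tau : float
        Duration of the rectangular window, in seconds.  Unused for the
        alpha kernel.
    eps0 : float
        Amplitude scale of the alpha EPSP (peak value ``eps0 / 2``).
    tau_alpha : float
        Time constant of the alpha kernel, in seconds.
    """

    kind: str = "rectangular"
    tau: float = 0.015
    eps0: float = 2.8
    tau_alpha: float = 0.0085
    t1: float = field(default=_T1, repr=False)
    t2: float = field(default=_T2, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("rectangular", "alpha"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rectangular" and self.tau <= 0:
            raise ValueError("rectangular kernel needs tau > 0")
        if self.kind == "alpha" and self.tau_alpha <= 0:
            raise ValueError("alpha kernel needs tau_alpha > 0")

    @property
    def support(self) -> float:
        """Length of the interval on which the kernel is non-zero."""
        if self.kind == "rectangular":
            return self.tau
        return (self.t2 - self.t1) * self.tau_alpha

    @property
    def peak_time(self) -> float:
        """Time after the presynaptic spike at which the kernel peaks."""
        if self.kind == "rectangular":
            return 0.0
        return (1.0 - self.t1) * self.tau_alpha

    @property
    def peak_value(self) -> float:
        if self.kind == "rectangular":
            return 1.0
        return self.eps0 * 0.5

    def __call__(self, dt: float) -> float:
        if self.kind == "rectangular":
            return rect_psp(dt, self.tau)
        return alpha_psp(dt, self)


def rect_psp(dt: float, tau: float) -> float:
    """Rectangular PSP: 1 on the half-open window ``[0, tau)``, else 0."""
    if tau <= 0:
        raise ValueError("rectangular kernel needs tau > 0")
    return 1.0 if 0.0 <= dt < tau else 0.0


def alpha_psp(dt: float, kernel: PSPKernel) -> float:
    """Truncated alpha EPSP evaluated ``dt`` seconds after the spike.

    ``eps0 * (e*(dt/tau_a + t1)*exp(-(dt/tau_a + t1)) - 1/2)`` on
    ``0 < dt < (t2 - t1) * tau_a`` and 0 outside; continuous at both
    edges because t1 and t2 are the half-height crossings.
    """
    if kernel.kind != "alpha":
        raise ValueError("alpha_psp needs an alpha kernel")
    ta = kernel.tau_alpha
    if dt <= 0.0 or dt >= (kernel.t2 - kernel.t1) * ta:
        return 0.0
    s = dt / ta + kernel.t1
    return kernel.eps0 * (math.e * s * math.exp(-s) - 0.5)
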