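"""Analytic layer: the mixture model implicitly defined by a module.

A trained association module encodes, through the synaptic weights and
biases of its hidden winner-take-all (WTA) neurons, a mixture of
multinomials p(a, z, x; theta) over the input variables x, the output
variable z and a one-hot hidden variable a (one binary component per
hidden neuron, plus a null component for "no recent spike").  This
module maps network weights to the natural parameters theta, evaluates
the model and its conditionals by exact enumeration, and provides the
KL objectives and mean-field update used to verify learning against
the theory.

Parameter mapping.  A weight w and bias b correspond to natural
parameters ``w_hat = T * (w + w_minus)`` and ``b_hat = T * (b +
b_minus)``, where ``w_minus``/``b_minus`` are the rule's baseline
offsets and ``T`` its potentiation scaling factor.  At ``T = 1`` this
is the plain affine shift of the theory; for general T it is the map
under which the STDP fixed points ``w = -w_minus + ln(p)/T`` land at
``w_hat = ln p``, i.e. at log-probabilities of the generating
distribution.  Fixed zero-value parameters are pinned at ``-V`` with a
large positive V, so states in which any variable is 0 carry a
negligible share of the model mass.

Normalisation residuals (the c0/c_ijl functions) are summed over the
learnable entries only (l != 0, m != 0); the pinned entries contribute
``exp(-V)`` and are ignored by convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "Theta",
    "DistributionTable",
    "theta_from_weights",
    "weights_from_theta",
    "joint_full",
    "joint_marginal",
    "conditional_z",
    "alpha_posterior",
    "normalization_residuals",
    "kl_objective",
    "network_objective",
    "mean_update",
    "em_fixed_point",
    "construct_theta",
]

_ENUM_GUARD = 10**6


# ----------------------------------------------------------------------
# probability tables
# ----------------------------------------------------------------------


class DistributionTable:
    """Dense probability table over a list of discrete variables.

    ``variables`` is a list of ``(name, values)`` pairs, with ``values``
    the explicit list of admissible integer values (e.g. ``[1, 2]`` for
    an external binary variable, ``[0, 1, 2]`` when the "no recent
    spike" zero state is included).  ``probs`` is a dense array with one
    axis per variable.
    """

    def __init__(self, variables, probs, normalized: bool = True):
        self.variables = [(str(n), list(v)) for n, v in variables]
        self.probs = np.asarray(probs, dtype=float)
        expected = tuple(len(v) for _, v in self.variables)
        if self.probs.shape != expected:
            raise ValueError(f"shape {self.probs.shape} != {expected}")
        if np.any(self.probs < -1e-15):
            raise ValueError("negative probability entry")
        if normalized and abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("table flagged normalized but does not sum to 1")
        self.normalized = normalized

    @property
    def names(self):
        return [n for n, _ in self.variables]

    def axis(self, name: str) -> int:
        return self.names.index(name)

    def prob(self, assignment: dict) -> float:
        idx = []
        for n, vals in self.variables:
            idx.append(vals.index(assignment[n]))
        return float(self.probs[tuple(idx)])

    def marginal(self, names) -> "DistributionTable":
        names = list(names)
        keep = [self.axis(n) for n in names]
        drop = tuple(ax for ax in range(self.probs.ndim) if ax not in keep)
        p = self.probs.sum(axis=drop)
        # after the sum, kept axes sit in ascending original order
        p = np.moveaxis(
            p,
            [sorted(keep).index(a) for a in keep],
            range(len(keep)),
        )
        return DistributionTable(
            [(n, self.variables[self.axis(n)][1]) for n in names],
            p,
            normalized=self.normalized,
        )

    def condition(self, evidence: dict) -> "DistributionTable":
        """Table over the remaining variables given exact evidence."""
        idx = [slice(None)] * self.probs.ndim
        rest = []
        for ax, (n, vals) in enumerate(self.variables):
            if n in evidence:
                idx[ax] = vals.index(evidence[n])
            else:
                rest.append((n, vals))
        p = self.probs[tuple(idx)]
        s = p.sum()
        if s <= 0:
            raise ValueError("conditioning on zero-probability evidence")
        return DistributionTable(rest, p / s)

    def assignments(self):
        """Iterate ``(dict, probability)`` in lexicographic order."""
        names = self.names
        values = [v for _, v in self.variables]
        for combo, p in zip(itertools.product(*values), self.probs.flat):
            yield dict(zip(names, combo)), float(p)

    def align_to(self, other: "DistributionTable") -> np.ndarray:
        """This table's probabilities embedded on ``other``'s domain."""
        if self.names != other.names:
            raise ValueError("variable names/order differ")
        out = np.zeros_like(other.probs)
        for assignment, p in self.assignments():
            idx = tuple(
                vals.index(assignment[n]) for n, vals in other.variables
            )
            out[idx] += p
        return out

    def total_variation(self, other: "DistributionTable") -> float:
        mine = self.align_to(self._union_domain(other))
        theirs = other.align_to(self._union_domain(other))
        return 0.5 * float(np.abs(mine - theirs).sum())

    def _union_domain(self, other: "DistributionTable") -> "DistributionTable":
        if self.names != other.names:
            raise ValueError("variable names/order differ")
        variables = []
        for (n, va), (_, vb) in zip(self.variables, other.variables):
            variables.append((n, sorted(set(va) | set(vb))))
        shape = tuple(len(v) for _, v in variables)
        return DistributionTable(variables, np.zeros(shape), normalized=False)

    def kl_from(self, model: "DistributionTable"):
        """KL(self || model) in nats; ``inf`` (flagged) on missing support."""
        dom = self._union_domain(model)
        p = self.align_to(dom)
        q = model.align_to(dom)
        mask = p > 0
        if np.any(q[mask] <= 0):
            return math.inf, True
        return float(np.sum(p[mask] * np.log(p[mask] / q[mask]))), False

    # -- text round-trip ------------------------------------------------

    def dumps(self) -> str:
        lines = ["# " + "\t".join(self.names + ["probability"])]
        for assignment, p in self.assignments():
            vals = [str(assignment[n]) for n in self.names]
            lines.append("\t".join(vals + [repr(p)]))
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "DistributionTable":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].lstrip("# ").split("\t")
        names = header[:-1]
        rows = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            rows.append(([int(v) for v in parts[:-1]], float(parts[-1])))
        values = [sorted({r[0][i] for r in rows}) for i in range(len(names))]
        shape = tuple(len(v) for v in values)
        p = np.zeros(shape)
        for vals, prob in rows:
            p[tuple(values[i].index(v) for i, v in enumerate(vals))] = prob
        return cls(
            list(zip(names, values)), p, normalized=abs(p.sum() - 1) < 1e-9
        )

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def load(cls, path) -> "DistributionTable":
        with open(path) as fh:
            return cls.loads(fh.read())


# ----------------------------------------------------------------------
# theta
# ----------------------------------------------------------------------


@dataclass
class Theta:
    """Natural parameters of one module's generative model.

    ``w_hat[i]`` has shape ``(M_i + 1, C)`` with row 0 pinned at ``-V``;
    ``b_hat`` has one entry per hidden component.  ``comp_l``/``comp_j``
    give each component's output value l (1-based) and within-group
    index j.  The null component (no neuron active) has prior parameter
    ``T * b_minus`` and per-input likelihood parameter ``T * w_minus``
    for non-zero values, ``-V`` for value 0.
    """

    M: tuple
    J: tuple
    w_hat: list
    b_hat: np.ndarray
    w_minus: float
    b_minus: float
    T: float = 1.0
    V: float = 50.0
    input_names: tuple = ()
    output_name: str = "z"

    def __post_init__(self):
        self.M = tuple(int(m) for m in self.M)
        self.J = tuple(int(j) for j in self.J)
        if any(m < 2 for m in self.M):
            raise ValueError("input cardinalities must be >= 2")
        if any(j < 1 for j in self.J):
            raise ValueError("hidden counts must be >= 1")
        C = sum(self.J)
        self.b_hat = np.asarray(self.b_hat, dtype=float)
        if self.b_hat.shape != (C,):
            raise ValueError("b_hat shape mismatch")
        self.w_hat = [np.asarray(w, dtype=float) for w in self.w_hat]
        for m, w in zip(self.M, self.w_hat):
            if w.shape != (m + 1, C):
                raise ValueError("w_hat shape mismatch")
        if not all(
            np.isfinite(w).all() for w in self.w_hat
        ) or not np.isfinite(self.b_hat).all():
            raise ValueError("theta entries must be finite")
        if self.V <= 0:
            raise ValueError("V must be positive")
        comp_l, comp_j = [], []
        for l, jl in enumerate(self.J, start=1):
            for j in range(1, jl + 1):
                comp_l.append(l)
                comp_j.append(j)
        self.comp_l = np.array(comp_l)
        self.comp_j = np.array(comp_j)
        if not self.input_names:
            self.input_names = tuple(f"x{i + 1}" for i in range(len(self.M)))

    @property
    def n_inputs(self) -> int:
        return len(self.M)

    @property
    def n_components(self) -> int:
        return len(self.b_hat)

    @property
    def L(self) -> int:
        return len(self.J)

    def components_of(self, l: int) -> np.ndarray:
        return np.nonzero(self.comp_l == l)[0]

    # log weight of (a=c, x) before normalization, for all x and c
    def _log_scores(self) -> np.ndarray:
        """Array of shape (M_1+1, ..., M_I+1, C+1); last slot = null."""
        C = self.n_components
        shape = tuple(m + 1 for m in self.M)
        n_x = int(np.prod(shape))
        if n_x * (C + 1) > _ENUM_GUARD:
            raise ValueError("model too large to enumerate")
        logw = np.zeros(shape + (C + 1,))
        logw[..., :C] += self.b_hat
        null_b = self.T * self.b_minus
        null_w = self.T * self.w_minus
        logw[..., C] += null_b
        for i, m in enumerate(self.M):
            wh = np.concatenate(
                [self.w_hat[i], np.full((m + 1, 1), null_w)], axis=1
            )
            wh[0, C] = -self.V
            sl = [None] * len(self.M) + [slice(None)]
            sl[i] = slice(None)
            logw = logw + wh[tuple(sl)]
        return logw

    def log_norm(self) -> float:
        return float(logsumexp(self._log_scores()))


def theta_from_weights(weights, biases, cfg, M, J, V: float = 50.0,
                       input_names=(), output_name="z") -> Theta:
    """Map network weights/biases to generative-model parameters.

    ``weights[i]`` has shape ``(M_i, C)`` (values 1..M_i only); the
    pinned zero-value rows are added here.  ``cfg`` supplies
    ``w_minus``, ``b_minus`` and ``T``.
    """
    M = tuple(M)
    C = sum(J)
    w_hat = []
    for i, m in enumerate(M):
        w = np.asarray(weights[i], dtype=float)
        if w.shape != (m, C):
            raise ValueError(f"weights[{i}] shape {w.shape} != {(m, C)}")
        wh = np.full((m + 1, C), -float(V))
        wh[1:, :] = cfg.T * (w + cfg.w_minus)
        w_hat.append(wh)
    b_hat = cfg.T * (np.asarray(biases, dtype=float) + cfg.b_minus)
    return Theta(
        M=M,
        J=tuple(J),
        w_hat=w_hat,
        b_hat=b_hat,
        w_minus=cfg.w_minus,
        b_minus=cfg.b_minus,
        T=cfg.T,
        V=float(V),
        input_names=tuple(input_names),
        output_name=output_name,
    )


def weights_from_theta(theta: Theta):
    """Inverse of :func:`theta_from_weights` (learnable entries only)."""
    weights = [
        w[1:, :] / theta.T - theta.w_minus for w in theta.w_hat
    ]
    biases = theta.b_hat / theta.T - theta.b_minus
    return weights, biases


# ----------------------------------------------------------------------
# evaluation by enumeration
# ----------------------------------------------------------------------


def joint_full(theta: Theta, a, z: int, x) -> float:
    """Exact p(a, z, x; theta) with the partition function enumerated.

    ``a`` is ``(l, j)`` with 1-based l and j, or ``(0, 1)`` for the null
    component; ``x`` is a sequence of input values (0..M_i).
    """
    l, j = a
    if z != l:
        return 0.0  # the z|a link is deterministic
    x = tuple(int(v) for v in x)
    if len(x) != theta.n_inputs or any(
        not 0 <= v <= m for v, m in zip(x, theta.M)
    ):
        raise ValueError("invalid input assignment")
    logw = theta._log_scores()
    logA = logsumexp(logw)
    C = theta.n_components
    if l == 0:
        if j != 1:
            raise ValueError("null component is (0, 1)")
        c = C
    else:
        cands = np.nonzero((theta.comp_l == l) & (theta.comp_j == j))[0]
        if len(cands) == 0:
            raise ValueError(f"no hidden component ({l}, {j})")
        c = int(cands[0])
    return float(np.exp(logw[x + (c,)] - logA))


def joint_marginal(theta: Theta, include_components: bool = False):
    """Exact table p(z, x; theta) over z in 0..L and x_i in 0..M_i.

    With ``include_components`` also returns the per-component tables
    p(x, z=l, a=(l,j); theta) (the mixture components).
    """
    logw = theta._log_scores()
    logA = logsumexp(logw)
    p_axc = np.exp(logw - logA)  # (..., C+1)
    C = theta.n_components
    L = theta.L
    shape = tuple(m + 1 for m in theta.M)
    out = np.zeros((L + 1,) + shape)
    out[0] = p_axc[..., C]
    for c in range(C):
        out[theta.comp_l[c]] += p_axc[..., c]
    variables = [(theta.output_name, list(range(L + 1)))] + [
        (n, list(range(m + 1)))
        for n, m in zip(theta.input_names, theta.M)
    ]
    table = DistributionTable(variables, out)
    if not include_components:
        return table
    comps = [
        DistributionTable(variables[1:], p_axc[..., c], normalized=False)
        for c in range(C)
    ]
    return table, comps


def conditional_z(theta: Theta, x, tau: float = 0.015):
    """p(z | x; theta) over z = 0..L, plus predicted output intensities.

    The intensity of output neuron l predicted from theta equals the sum
    of its hidden neurons' intensities ``(1/tau) exp(u_j)``; at T=1 this
    coincides with ``(1/tau) p(z=l|x) / p(z=0|x)``.
    """
    x = tuple(int(v) for v in x)
    if any(not 1 <= v <= m for v, m in zip(x, theta.M)):
        raise ValueError("x must be a full non-zero assignment")
    logw = theta._log_scores()[x]  # (C+1,)
    C = theta.n_components
    logZ = logsumexp(logw)
    p_a = np.exp(logw - logZ)
    cond = np.zeros(theta.L + 1)
    cond[0] = p_a[C]
    for c in range(C):
        cond[theta.comp_l[c]] += p_a[c]
    # network-side intensities from the inverse-mapped weights
    weights, biases = weights_from_theta(theta)
    u = biases.copy()
    for i, v in enumerate(x):
        u = u + weights[i][v - 1, :]
    rates_c = np.exp(u) / tau
    rates = np.zeros(theta.L + 1)
    for c in range(C):
        rates[theta.comp_l[c]] += rates_c[c]
    return cond, rates[1:]


def alpha_posterior(theta: Theta, x, z: int) -> np.ndarray:
    """Posterior over the hidden neurons of subpopulation z given (x, z)."""
    x = tuple(int(v) for v in x)
    if not 1 <= z <= theta.L:
        raise ValueError("z out of range")
    logw = theta._log_scores()[x]
    comps = theta.components_of(z)
    lw = logw[comps]
    return np.exp(lw - logsumexp(lw))


def normalization_residuals(theta: Theta):
    """Residuals of the normalization constraints.

    ``c0 = sum_c exp(b_hat_c) - 1`` over the learnable components and,
    per input i and component c, ``c_ic = sum_{m>=1} exp(w_hat_imc) - 1``.
    Returns ``(c0, c_ic array of shape (I, C), max_abs)``.
    """
    c0 = float(np.exp(theta.b_hat).sum() - 1.0)
    C = theta.n_components
    cw = np.zeros((theta.n_inputs, C))
    for i in range(theta.n_inputs):
        cw[i] = np.exp(theta.w_hat[i][1:, :]).sum(axis=0) - 1.0
    return c0, cw, max(abs(c0), float(np.abs(cw).max()) if cw.size else 0.0)


def kl_objective(theta: Theta, target: DistributionTable):
    """U = KL(p* || p(.; theta)) and its conditional/marginal split.

    Returns a dict with ``U``, ``J`` (mean conditional KL), ``kl_x``
    (input-marginal KL) and ``infinite`` (True when the target has mass
    where the model has none, in which case U is +inf).
    """
    model = joint_marginal(theta)
    names = model.names
    target = target.marginal(names) if target.names != names else target
    dom = target._union_domain(model)
    p = target.align_to(dom)
    q = model.align_to(dom)
    mask = p > 0
    if np.any(q[mask] <= 0):
        return {"U": math.inf, "J": math.inf, "kl_x": math.inf, "infinite": True}
    U = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    # decomposition: U = J + KL(p*(x) || p(x; theta))
    px_p = p.sum(axis=0)
    px_q = q.sum(axis=0)
    mx = px_p > 0
    kl_x = float(np.sum(px_p[mx] * np.log(px_p[mx] / px_q[mx])))
    return {"U": U, "J": U - kl_x, "kl_x": kl_x, "infinite": False}


def network_objective(thetas, targets) -> float:
    """Sum of per-module KLs, one (theta, marginal target) pair each."""
    total = 0.0
    for theta, target in zip(thetas, targets):
        total += kl_objective(theta, target)["U"]
    return total


# ----------------------------------------------------------------------
# learning-dynamics oracle
# ----------------------------------------------------------------------


@dataclass
class MeanUpdate:
    """Expected parameter update h_bar(theta) over the complete data."""

    h_b: np.ndarray  # (C,)
    h_w: list  # per input, (M_i, C) for m = 1..M_i
    p_star_a: np.ndarray  # marginal p*(a_c = 1; theta)

    def max_abs(self) -> float:
        vals = [float(np.abs(self.h_b).max())]
        vals += [float(np.abs(h).max()) for h in self.h_w]
        return max(vals)


def mean_update(theta: Theta, target: DistributionTable) -> MeanUpdate:
    """Exact E[delta theta] of the T=1 rules over p*(x,z) p(a|x,z; theta).

    ``delta w_hat = a * (x e^{-w_hat} - 1)`` and ``delta b_hat =
    a e^{-b_hat} - 1`` per presented example (the per-tau form of the
    spike-triggered growth plus constant decay).
    """
    names = [theta.output_name] + list(theta.input_names)
    target = target.marginal(names) if target.names != names else target
    C = theta.n_components
    Ea = np.zeros(C)
    Eax = [np.zeros((m, C)) for m in theta.M]
    for assignment, p in target.assignments():
        if p <= 0:
            continue
        z = assignment[theta.output_name]
        x = tuple(assignment[n] for n in theta.input_names)
        if z == 0 or any(v == 0 for v in x):
            raise ValueError("target must put no mass on zero values")
        post = alpha_posterior(theta, x, z)
        comps = theta.components_of(z)
        Ea[comps] += p * post
        for i, v in enumerate(x):
            Eax[i][v - 1, comps] += p * post
    h_b = Ea * np.exp(-theta.b_hat) - 1.0
    h_w = []
    for i, m in enumerate(theta.M):
        h = Eax[i] * np.exp(-theta.w_hat[i][1:, :]) - Ea[None, :]
        h_w.append(h)
    return MeanUpdate(h_b=h_b, h_w=h_w, p_star_a=Ea)


def em_fixed_point(
    target: DistributionTable,
    M,
    J,
    iters: int = 200,
    seed: int = 0,
    V: float = 50.0,
    w_minus: float = 2.5 * math.log(0.2),
    b_minus: float = -15.0,
) -> Theta:
    """Iterate the self-consistency equations to an EM fixed point.

    ``b_hat = log p*(a_c; theta)``, ``w_hat = log p*(x_im | a_c; theta)``
    — exact (batch) EM for the mixture of multinomials.
    """
    rng = np.random.default_rng(seed)
    C = sum(J)
    theta = Theta(
        M=tuple(M),
        J=tuple(J),
        w_hat=[
            np.vstack(
                [
                    np.full((1, C), -V),
                    np.log(
                        _normalized(rng.uniform(0.5, 1.5, size=(m, C)), axis=0)
                    ),
                ]
            )
            for m in M
        ],
        b_hat=np.log(_normalized(rng.uniform(0.5, 1.5, size=C))),
        w_minus=w_minus,
        b_minus=b_minus,
        V=V,
    )
    floor = math.exp(-V)
    for _ in range(iters):
        mu = mean_update(theta, target)
        Ea = np.maximum(mu.p_star_a, floor)
        b_hat = np.log(Ea / Ea.sum())
        w_hat = []
        for i, m in enumerate(M):
            Eax = (mu.h_w[i] + Ea[None, :]) * np.exp(theta.w_hat[i][1:, :])
            lik = np.maximum(Eax, floor) / Ea[None, :]
            lik = _normalized(lik, axis=0)
            wh = np.vstack([np.full((1, C), -V), np.log(lik)])
            w_hat.append(wh)
        theta = Theta(
            M=theta.M,
            J=theta.J,
            w_hat=w_hat,
            b_hat=b_hat,
            w_minus=w_minus,
            b_minus=b_minus,
            V=V,
            input_names=theta.input_names,
            output_name=theta.output_name,
        )
    return theta


def _normalized(arr, axis=None):
    arr = np.asarray(arr, dtype=float)
    return arr / arr.sum(axis=axis, keepdims=axis is not None)


def construct_theta(
    target: DistributionTable,
    eps: float = 1e-4,
    V: float = 50.0,
    w_minus: float = 2.5 * math.log(0.2),
    b_minus: float = -15.0,
    input_names=(),
    output_name=None,
) -> Theta:
    """Point-mass construction: one hidden component per input assignment.

    Component (l, j) carries the j-th assignment xi of the inputs with
    prior ``p*(z=l, x=xi)`` and near-deterministic likelihoods
    (probability ``1 - eps*(M_i - 1)`` on the carried value, ``eps``
    elsewhere).  As ``eps -> 0`` the model reproduces the target table
    exactly; the construction realises the computability condition for
    sampling networks with analytically set parameters.
    """
    output_name = output_name or target.names[0]
    in_names = [n for n in target.names if n != output_name]
    if input_names:
        in_names = list(input_names)
    target = target.marginal([output_name] + in_names)
    zvals = target.variables[0][1]
    if 0 in zvals:
        raise ValueError("target must be over non-zero values")
    L = max(zvals)
    M = tuple(max(v) for _, v in target.variables[1:])
    x_assigns = list(itertools.product(*[range(1, m + 1) for m in M]))
    Jl = len(x_assigns)
    J = tuple(Jl for _ in range(L))
    C = Jl * L
    floor = math.exp(-V)
    b_hat = np.empty(C)
    w_hat = [np.full((m + 1, C), -V) for m in M]
    c = 0
    for l in range(1, L + 1):
        for xi in x_assigns:
            try:
                p = target.prob(
                    {output_name: l, **dict(zip(in_names, xi))}
                )
            except ValueError:
                p = 0.0
            b_hat[c] = math.log(max(p, floor))
            for i, m in enumerate(M):
                on = math.log(max(1.0 - eps * (m - 1), floor))
                off = math.log(max(eps, floor))
                for mv in range(1, m + 1):
                    w_hat[i][mv, c] = on if mv == xi[i] else off
            c += 1
    return Theta(
        M=M,
        J=J,
        w_hat=w_hat,
        b_hat=b_hat,
        w_minus=w_minus,
        b_minus=b_minus,
        V=V,
        input_names=tuple(in_names),
        output_name=output_name,
    )
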