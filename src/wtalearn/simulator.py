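"""Event-driven simulation of stochastic point-neuron networks.

Neurons fire as inhomogeneous point processes with intensity
``rho(t) = (1/tau) * exp(u(t))`` outside an absolute refractory period
of duration ``tau``; the membrane potential ``u(t)`` is the bias plus
the sum of weighted PSP traces of the most recent presynaptic spikes
plus any injected currents.

The engine is exact for piecewise-constant intensities (all-rectangular
input kernels): between structural events the intensity is constant and
the next spike is drawn by inverse-CDF sampling.  With alpha-shaped
EPSPs the next spike is drawn by thinning against a certified upper
bound computed per segment from the unimodal kernel shape; a segment
never extends past the next scheduled discontinuity (current switch or
PSP-window expiry), so the bound is valid throughout.

Randomness comes from one root seed expanded into independent
per-neuron substreams, so adding a neuron leaves every other neuron's
draws untouched and identical seeds give bit-identical spike records.
"""

from __future__ import annotations

import logging
import math
from array import array
from heapq import heappush, heappop

import numpy as np

from .network import NetworkSpec, CurrentSchedule, SpikeRecord
from .plasticity import PlasticityConfig

__all__ = ["Simulator", "simulate", "SimulationError"]

_log = logging.getLogger("wtalearn.simulator")

_NEG_INF = float("-inf")
_RECHECK, _CAND = 0, 1


class SimulationError(RuntimeError):
    pass


class _CumulativeRate:
    """Cumulative integral H(t) of a piecewise-linear rate schedule.

    Precomputed per segment as ``H_i + r_i (t - t_i) + s_i (t - t_i)^2 / 2``
    so evaluation is a short scan plus one closed-form expression.
    """

    def __init__(self, schedule):
        pts = schedule.points
        ts, rs, slopes, Hs = [], [], [], []
        H = 0.0
        for k in range(len(pts)):
            t0, r0 = pts[k]
            if k + 1 < len(pts):
                t1, r1 = pts[k + 1]
                if t1 == t0:
                    continue
                sl = (r1 - r0) / (t1 - t0)
            else:
                t1, sl = math.inf, 0.0
            ts.append(t0)
            rs.append(r0)
            slopes.append(sl)
            Hs.append(H)
            if t1 < math.inf:
                H += 0.5 * (r0 + pts[k + 1][1]) * (t1 - t0)
        self.ts = ts
        self.rs = rs
        self.slopes = slopes
        self.Hs = Hs
        self._r_first = pts[0][1]

    def __call__(self, t: float) -> float:
        ts = self.ts
        if t <= ts[0]:
            return self._r_first * (t - ts[0])
        for i in range(len(ts) - 1, -1, -1):
            ti = ts[i]
            if t >= ti:
                dt = t - ti
                return self.Hs[i] + (self.rs[i] + 0.5 * self.slopes[i] * dt) * dt
        return 0.0


class Simulator:
    """Stateful event-driven simulator for one :class:`NetworkSpec`.

    Parameters
    ----------
    net : NetworkSpec
    seed : int
        Root seed; expanded into per-neuron substreams.
    plasticity : PlasticityConfig or dict, optional
        Enables the learning rules on synapses/neurons flagged plastic.
        A dict maps neuron ids to per-neuron configs (modules of a
        composite network may use different offsets and clip bounds);
        afferent plastic synapses follow their postsynaptic neuron's
        config.  Updates fire only while :attr:`learning` is True.
    record : bool or sequence of int
        Record all spikes (True), none (False), or a subset of neurons.
    """

    def __init__(
        self,
        net: NetworkSpec,
        seed: int = 0,
        plasticity: PlasticityConfig | None = None,
        record=True,
        rate_cap: float = 1e12,
        horizon: float = 0.5,
    ):
        self.net = net
        n = len(net.neurons)
        self.n = n
        self.bias = [float(nr.bias) for nr in net.neurons]
        self.refr = [float(nr.refractory) for nr in net.neurons]
        self.plastic_bias = [bool(nr.plastic_bias) for nr in net.neurons]
        for i, nr in enumerate(net.neurons):
            if not math.isfinite(nr.bias):
                raise SimulationError(f"non-finite bias on neuron {i}")

        # afferent (incoming synapse) arrays, grouped by postsynaptic neuron
        self.aff_pre = [[] for _ in range(n)]
        self.aff_w = [[] for _ in range(n)]
        self.aff_kind = [[] for _ in range(n)]  # 0 rect, 1 alpha
        self.aff_sup = [[] for _ in range(n)]
        self.aff_ta = [[] for _ in range(n)]  # tau_alpha
        self.aff_e0 = [[] for _ in range(n)]
        self.aff_t1 = [[] for _ in range(n)]
        self.aff_peak = [[] for _ in range(n)]  # peak time for alpha
        self.aff_last = [[] for _ in range(n)]
        # absolute expiry times, computed with the same float expression
        # as refractory ends so that a window anchored at a neuron's own
        # spike is never judged active at that neuron's refractory end
        self.aff_exp = [[] for _ in range(n)]
        self.aff_plastic = [[] for _ in range(n)]
        self.eff = [[] for _ in range(n)]  # (post, slot in post's afferent arrays)
        self.syn_slot = []  # synapse index -> (post, slot)
        for sy in net.synapses:
            if not math.isfinite(sy.weight):
                raise SimulationError(f"non-finite weight {sy.pre}->{sy.post}")
            j = sy.post
            k = sy.kernel
            slot = len(self.aff_pre[j])
            self.aff_pre[j].append(sy.pre)
            self.aff_w[j].append(float(sy.weight))
            if k.kind == "rectangular":
                self.aff_kind[j].append(0)
                self.aff_sup[j].append(k.tau)
                self.aff_ta[j].append(0.0)
                self.aff_e0[j].append(0.0)
                self.aff_t1[j].append(0.0)
                self.aff_peak[j].append(0.0)
            else:
                self.aff_kind[j].append(1)
                self.aff_sup[j].append(k.support)
                self.aff_ta[j].append(k.tau_alpha)
                self.aff_e0[j].append(k.eps0)
                self.aff_t1[j].append(k.t1)
                self.aff_peak[j].append(k.peak_time)
            self.aff_last[j].append(_NEG_INF)
            self.aff_exp[j].append(_NEG_INF)
            self.aff_plastic[j].append(bool(sy.plastic))
            self.eff[sy.pre].append((j, slot))
            self.syn_slot.append((j, slot))
        self.has_plastic = [any(self.aff_plastic[i]) for i in range(n)]

        if plasticity is None:
            self.pcfg = [None] * n
        elif isinstance(plasticity, dict):
            self.pcfg = [plasticity.get(i) for i in range(n)]
        else:
            self.pcfg = [plasticity] * n
        self.learning = any(c is not None for c in self.pcfg)
        cums: dict[int, _CumulativeRate] = {}
        self._eta_b_cum = [None] * n
        for i, c in enumerate(self.pcfg):
            if c is not None:
                key = id(c.eta_b)
                if key not in cums:
                    cums[key] = _CumulativeRate(c.eta_b)
                self._eta_b_cum[i] = cums[key]
        self.bias_t = [0.0] * n  # time up to which bias decay is committed

        self.rate_cap = float(rate_cap)
        self.horizon = float(horizon)
        self.cur_amp = [0.0] * n
        self._cur_events = []  # sorted (t, [(neuron, delta), ...])
        self._cur_ptr = 0
        self.t = 0.0
        self._cap_warned = False
        self.refr_end = [_NEG_INF] * n
        self.version = [0] * n
        self._heap = []

        if record is True:
            self._rec_mask = None
        elif record is False:
            self._rec_mask = [False] * n
        else:
            self._rec_mask = [False] * n
            for i in record:
                self._rec_mask[i] = True
        self._rec_t = array("d")
        self._rec_i = array("q")

        ss = np.random.SeedSequence(int(seed))
        import random as _random

        self.rngs = [
            _random.Random(int(c.generate_state(1, np.uint64)[0]))
            for c in ss.spawn(n)
        ]
        self._started = False

    # ------------------------------------------------------------------
    # current / protocol handling
    # ------------------------------------------------------------------

    def add_current_events(self, events) -> None:
        """Add amplitude-delta events: iterable of ``(t, [(neuron, delta)])``.

        Must be called before the affected times are simulated.
        """
        evs = sorted((float(t), list(ds)) for t, ds in events)
        if self._cur_events and self._cur_ptr < len(self._cur_events):
            merged = self._cur_events[self._cur_ptr :] + evs
            merged.sort(key=lambda e: e[0])
            self._cur_events = merged
            self._cur_ptr = 0
        else:
            self._cur_events = evs
            self._cur_ptr = 0

    @staticmethod
    def events_from_schedule(schedule: CurrentSchedule):
        evs: dict[float, list] = {}
        for p in schedule:
            evs.setdefault(p.t_start, []).append((p.neuron, p.amplitude))
            evs.setdefault(p.t_end, []).append((p.neuron, -p.amplitude))
        return sorted(evs.items())

    # ------------------------------------------------------------------
    # membrane potential
    # ------------------------------------------------------------------

    def _bias_eff(self, i: int, t: float) -> float:
        b = self.bias[i]
        if self.learning and self.plastic_bias[i] and self.pcfg[i] is not None:
            cum = self._eta_b_cum[i]
            d = cum(t) - cum(self.bias_t[i])
            if d > 0.0:
                b = b - d
                bm = self.pcfg[i].b_min
                if b < bm:
                    b = bm
        return b

    def potential(self, i: int, t: float) -> float:
        """Exact membrane potential of neuron ``i`` at time ``t``."""
        u = self._bias_eff(i, t) + self.cur_amp[i]
        last = self.aff_last[i]
        exp_ = self.aff_exp[i]
        w = self.aff_w[i]
        kind = self.aff_kind[i]
        ta = self.aff_ta[i]
        e0 = self.aff_e0[i]
        t1 = self.aff_t1[i]
        for k in range(len(last)):
            ls = last[k]
            if ls == _NEG_INF or t >= exp_[k] or t < ls:
                continue
            if kind[k] == 0:
                u += w[k]
            elif t > ls:
                s = (t - ls) / ta[k] + t1[k]
                u += w[k] * e0[k] * (math.e * s * math.exp(-s) - 0.5)
        return u

    def intensity(self, i: int, t: float) -> float:
        """Firing intensity in events/second (0 during refractoriness)."""
        if t < self.refr_end[i]:
            return 0.0
        u = self.potential(i, t)
        return min(math.exp(u), self.rate_cap * self.refr[i]) / self.refr[i]

    # ------------------------------------------------------------------
    # scheduling
    # ------------------------------------------------------------------

    def _schedule(self, i: int, t: float, t_end: float) -> None:
        self.version[i] += 1
        v = self.version[i]
        heap = self._heap
        re = self.refr_end[i]
        if t < re:
            heappush(heap, (re, i, _RECHECK, v))
            return
        # segment end: next known discontinuity affecting this neuron
        # (current switch or rectangular-window expiry; alpha kernels
        # vanish continuously at their support end, so no cap needed)
        if self._cur_ptr < len(self._cur_events):
            t_seg = self._cur_events[self._cur_ptr][0]
            if t_seg > t_end:
                t_seg = t_end
        else:
            t_seg = t_end
        th = t + self.horizon
        if th < t_seg:
            t_seg = th
        last = self.aff_last[i]
        exp_ = self.aff_exp[i]
        w = self.aff_w[i]
        kind = self.aff_kind[i]
        sup = self.aff_sup[i]
        ta = self.aff_ta[i]
        e0 = self.aff_e0[i]
        t1 = self.aff_t1[i]
        peak = self.aff_peak[i]
        nk = len(last)
        for k in range(nk):
            if kind[k] == 0:
                ex = exp_[k]
                if t < ex < t_seg:
                    t_seg = ex
        if t_seg <= t:
            t_seg = t + 1e-12
        # coarse upper bound of u over [t, t_seg); every active
        # rectangular window spans the whole segment by construction
        u = self._bias_eff(i, t) + self.cur_amp[i]
        alpha_active = False
        for k in range(nk):
            ls = last[k]
            if ls == _NEG_INF or t >= exp_[k]:
                continue
            if kind[k] == 0:
                u += w[k]
            else:
                alpha_active = True
                dta = t - ls
                dtb = t_seg - ls
                if dtb > sup[k]:
                    dtb = sup[k]
                sa = dta / ta[k] + t1[k]
                ea = e0[k] * (math.e * sa * math.exp(-sa) - 0.5) if dta > 0 else 0.0
                sb = dtb / ta[k] + t1[k]
                eb = e0[k] * (math.e * sb * math.exp(-sb) - 0.5) if dtb < sup[k] else 0.0
                if w[k] > 0.0:
                    if dta < peak[k] < dtb:
                        u += w[k] * (e0[k] * 0.5)
                    else:
                        u += w[k] * (ea if ea > eb else eb)
                else:
                    u += w[k] * (ea if ea < eb else eb)
        if not math.isfinite(u):
            raise SimulationError(
                f"unbounded intensity for neuron {i} "
                f"({self.net.neurons[i].name or 'unnamed'}) at t={t:.6f}"
            )
        refr_i = self.refr[i]
        cap = self.rate_cap * refr_i
        ucap = math.log(cap)
        rng = self.rngs[i]
        expovariate = rng.expovariate
        random = rng.random
        if u >= ucap:
            bound = cap
            if not self._cap_warned:
                self._cap_warned = True
                _log.warning(
                    "intensity of neuron %d capped at %.0e events/s",
                    i,
                    self.rate_cap,
                )
        else:
            bound = math.exp(u)
        if bound * (t_seg - t) / refr_i < 1e-7:
            # negligible spike probability over the whole segment
            heappush(heap, (t_seg, i, _RECHECK, v))
            return
        if not alpha_active:
            # u is exactly constant on the segment: inverse-CDF sampling
            s = t + expovariate(bound / refr_i)
            if s < t_seg:
                heappush(heap, (s, i, _CAND, v))
            else:
                heappush(heap, (t_seg, i, _RECHECK, v))
            return
        # adaptive thinning: sub-windows short enough that u moves by at
        # most 1, so the accept ratio never falls below exp(-2)
        base = self.cur_amp[i]
        if self.learning and self.plastic_bias[i] and self.pcfg[i] is not None:
            cum = self._eta_b_cum[i]
            b_committed = self.bias[i]
            b_from = cum(self.bias_t[i])
            b_floor = self.pcfg[i].b_min
        else:
            cum = None
            base += self.bias[i]
        _e = math.e
        _exp = math.exp

        def u_at(s):
            u = base
            if cum is not None:
                b = b_committed - (cum(s) - b_from)
                u += b if b > b_floor else b_floor
            for k in range(nk):
                ls = last[k]
                if ls == _NEG_INF or s >= exp_[k] or s <= ls:
                    continue
                if kind[k] == 0:
                    u += w[k]
                else:
                    sx = (s - ls) / ta[k] + t1[k]
                    u += w[k] * e0[k] * (_e * sx * _exp(-sx) - 0.5)
            return u

        s0 = t
        while True:
            u0 = base
            if cum is not None:
                b = b_committed - (cum(s0) - b_from)
                u0 += b if b > b_floor else b_floor
            slope = 0.0
            for k in range(nk):
                ls = last[k]
                if ls == _NEG_INF or s0 >= exp_[k] or s0 < ls:
                    continue
                wk = w[k]
                dt0 = s0 - ls
                if kind[k] == 0:
                    u0 += wk
                    continue
                sa = dt0 / ta[k] + t1[k]
                es = _exp(-sa)
                u0 += wk * e0[k] * (_e * sa * es - 0.5)
                d1 = 1.0 - sa
                sl = _e * es * (d1 if d1 > 0 else -d1)
                if sa < 2.0 and sl < 0.36787944117144233:
                    sl = 0.36787944117144233  # |d(e s exp(-s))/ds| at s=2
                slope += (wk if wk > 0 else -wk) * sl * e0[k] / ta[k]
            if slope > 1e-9:
                s1 = s0 + 1.0 / slope
                ub = u0 + 1.0
                if s1 > t_seg:
                    s1 = t_seg
            else:
                s1 = t_seg
                ub = u0
            B = _exp(ub) if ub < ucap else cap
            B /= refr_i
            if B * (s1 - s0) >= 1e-9:
                s = s0
                while True:
                    s += expovariate(B)
                    if s >= s1:
                        break
                    us = u_at(s)
                    rho = _exp(us) if us < ucap else cap
                    rho /= refr_i
                    if random() * B < rho:
                        heappush(heap, (s, i, _CAND, v))
                        return
            s0 = s1
            if s0 >= t_seg:
                heappush(heap, (t_seg, i, _RECHECK, v))
                return

    # ------------------------------------------------------------------
    # plasticity
    # ------------------------------------------------------------------

    def _apply_plasticity(self, i: int, t: float) -> None:
        cfg = self.pcfg[i]
        if cfg is None:
            return
        eta = cfg.eta(t)
        if eta > 0.0 and self.has_plastic[i]:
            w = self.aff_w[i]
            last = self.aff_last[i]
            plast = self.aff_plastic[i]
            tw = cfg.tau
            T = cfg.T
            wm = cfg.w_minus
            w_lo, w_hi = cfg.w_min, cfg.w_max
            for k in range(len(w)):
                if not plast[k]:
                    continue
                if t - last[k] <= tw:  # closed window [t - tau, t]
                    dw = math.exp(-T * (w[k] + wm)) - 1.0
                else:
                    dw = -1.0
                nw = w[k] + eta * dw
                if nw < w_lo:
                    nw = w_lo
                elif nw > w_hi:
                    nw = w_hi
                w[k] = nw
        if self.plastic_bias[i]:
            b = self._bias_eff(i, t)  # includes pending decay
            db = cfg.tau * math.exp(-cfg.T * (b + cfg.b_minus))
            b = b + cfg.eta_b(t) * db
            if b > cfg.b_max:
                b = cfg.b_max
            elif b < cfg.b_min:
                b = cfg.b_min
            self.bias[i] = b
            self.bias_t[i] = t

    def commit_biases(self, t: float | None = None) -> None:
        """Fold pending continuous bias decay into the stored biases."""
        if not self.learning:
            return
        t = self.t if t is None else t
        for i in range(self.n):
            if self.plastic_bias[i] and self.pcfg[i] is not None:
                self.bias[i] = self._bias_eff(i, t)
                self.bias_t[i] = t

    # ------------------------------------------------------------------
    # main loop
    # ------------------------------------------------------------------

    def run_until(self, t_stop: float) -> None:
        if t_stop < self.t:
            raise ValueError("cannot run backwards")
        if not self._started:
            for i in range(self.n):
                self._schedule(i, self.t, t_stop)
            self._started = True
        heap = self._heap
        version = self.version
        rec_mask = self._rec_mask
        rec_t = self._rec_t
        rec_i = self._rec_i
        aff_last = self.aff_last
        aff_exp = self.aff_exp
        aff_sup = self.aff_sup
        eff = self.eff
        refr = self.refr
        refr_end = self.refr_end
        cur_events = self._cur_events
        learning = self.learning
        while True:
            t_heap = heap[0][0] if heap else math.inf
            t_cur = (
                cur_events[self._cur_ptr][0]
                if self._cur_ptr < len(cur_events)
                else math.inf
            )
            if t_cur <= t_heap:
                if t_cur > t_stop:
                    break
                _, deltas = cur_events[self._cur_ptr]
                self._cur_ptr += 1
                self.t = t_cur
                touched = set()
                for nid, d in deltas:
                    self.cur_amp[nid] += d
                    touched.add(nid)
                for nid in touched:
                    self._schedule(nid, t_cur, t_stop)
                continue
            if t_heap > t_stop:
                break
            t, i, kind, v = heappop(heap)
            if v != version[i]:
                continue
            self.t = t
            if kind == _RECHECK:
                self._schedule(i, t, t_stop)
                continue
            # spike of neuron i
            if rec_mask is None or rec_mask[i]:
                rec_t.append(t)
                rec_i.append(i)
            refr_end[i] = t + refr[i]
            if learning:
                self._apply_plasticity(i, t)
            dirty = []
            for j, slot in eff[i]:
                aff_last[j][slot] = t
                aff_exp[j][slot] = t + aff_sup[j][slot]
                dirty.append(j)
            self._schedule(i, t, t_stop)
            seen = set()
            for j in dirty:
                if j not in seen:
                    seen.add(j)
                    self._schedule(j, t, t_stop)
        self.t = t_stop
        # force rescheduling at the next run_until call
        for i in range(self.n):
            version[i] += 1
        self._heap = []
        self._started = False

    def run(self, duration: float) -> SpikeRecord:
        if duration <= 0:
            raise ValueError("duration must be > 0")
        self.run_until(self.t + duration)
        self.commit_biases()
        return self.spike_record()

    def spike_record(self) -> SpikeRecord:
        return SpikeRecord(
            np.frombuffer(self._rec_t, dtype=float).copy(),
            np.frombuffer(self._rec_i, dtype=np.int64).copy(),
        )

    # ------------------------------------------------------------------
    # parameter access
    # ------------------------------------------------------------------

    def weights(self) -> np.ndarray:
        """Current synaptic weights, in NetworkSpec synapse order."""
        return np.array([self.aff_w[j][s] for j, s in self.syn_slot])

    def set_weights(self, values) -> None:
        for (j, s), v in zip(self.syn_slot, values):
            self.aff_w[j][s] = float(v)

    def biases(self) -> np.ndarray:
        """Current biases (pending decay committed up to current time)."""
        self.commit_biases()
        return np.array(self.bias, dtype=float)

    def set_biases(self, values) -> None:
        for i, v in enumerate(values):
            self.bias[i] = float(v)
            self.bias_t[i] = self.t


def simulate(
    net: NetworkSpec,
    schedule: CurrentSchedule | None = None,
    duration: float = 1.0,
    seed: int = 0,
    plasticity: PlasticityConfig | None = None,
    record=True,
) -> SpikeRecord:
    """One-shot simulation of ``net`` under a current schedule."""
    sim = Simulator(net, seed=seed, plasticity=plasticity, record=record)
    if schedule is not None and len(schedule):
        sim.add_current_events(Simulator.events_from_schedule(schedule))
    return sim.run(duration)
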