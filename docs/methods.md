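# Methods

This note records the model, the numerical choices, and the limits of
what the test suite shows.  It is written for a reader who wants to
modify or extend the package, not as a tutorial.

## Neuron and synapse model

Neurons are stochastic point processes: outside an absolute refractory
period of duration τ (default 0.015 s) a neuron fires with intensity
ρ(t) = (1/τ) exp(u(t)), where

    u(t) = b + Σ_k w_k ε_k(t − t_k^last) + I(t)

sums the bias, the weighted PSP traces of the *most recent* spike of
each presynaptic partner (last-spike replacement — overlapping PSPs
from the same synapse never sum), and any injected currents.  Two PSP
shapes are available: a rectangular window of value 1 on [0, τ), and a
truncated alpha EPSP ε(dt) = ε₀·(e·s·e^(−s) − ½) with s = dt/τ_α + t₁,
supported on (0, (t₂ − t₁)τ_α) where t₁, t₂ are the half-height
crossings of e·t·e^(−t); with ε₀ = 2.8 and τ_α = 8.5 ms the peak is
1.4 at ≈ 6.5 ms and the support ≈ 20.8 ms.  Inhibitory synapses always
use rectangular windows of duration τ, standing in for fast-spiking
inhibition.

## Event-driven simulation

The simulator is event-driven, not time-stepped, so there is no
discretisation error in any statistical test:

* With only rectangular inputs the intensity is piecewise constant
  between structural events (spikes, window expiries, current
  switches) and the next spike is drawn exactly by inverse-CDF
  sampling on each constant piece.
* With alpha EPSPs the next spike is drawn by thinning.  The segment
  between structural discontinuities is subdivided adaptively: each
  sub-window is short enough that u can move by at most 1 log-unit
  (bounded through each active kernel's maximal slope, which for the
  alpha shape is max(|ε′(dt₀)|, |ε′| at s = 2) on any forward
  window), so the thinning bound exp(u₀ + 1) is certified and the
  acceptance ratio never falls below e⁻².  This keeps the expected
  number of proposals per scheduling call O(1) even though intensities
  are exponential in u.
* Numerical guards: intensities are capped at 10¹² s⁻¹ (far beyond
  anything resolvable at τ = 15 ms), and a segment whose bound implies
  a spike probability below 10⁻⁷ is skipped wholesale; the affected
  neurons sit at u ≲ −10, where the true spike rate over such a
  segment is orders of magnitude below one event per simulation.
* Randomness: one root seed is expanded (`numpy` SeedSequence) into an
  independent substream per neuron, so identical seeds give
  bit-identical spike records and adding a neuron does not perturb the
  draws of the others.  Simultaneous events are ordered by (time,
  neuron id).
* PSP windows are half-open [t_spike, t_spike + τ), and each window's
  expiry is stored as an absolute time computed with the same floating
  point expression as refractory ends.  This matters: with τ equal to
  the refractory period, a neuron's own-window expiry and its
  refractory end coincide exactly, and recomputing the window edge by
  subtraction (`t − t_spike ≥ τ`) scatters by one ulp at large t —
  enough to make inhibitory neurons re-fire spuriously at window
  expiry and visibly distort long runs.

## Plasticity

At each spike of a hidden (α) neuron, every plastic afferent synapse
changes by η·Δw with Δw = e^(−T(w+w⁻)) − 1 if its presynaptic neuron
fired within the closed window [t − τ, t], else −1; the neuron's bias
grows by η′·τ·e^(−T(b+b⁻)) and decays between spikes at rate η′.  The
decay is accrued lazily (at the neuron's spikes, at membrane-potential
evaluations, and at checkpoints); because it is linear in time this is
identical to continuous decay.  Weights and biases are clipped to
[w_min, w_max] and [b_min, b_max] after every update.  The coincidence
window stays τ = 15 ms also in alpha-EPSP runs, although the alpha
support is ≈ 20.8 ms; the rule is tied to the coding window, not to
the kernel tail, and the residual mismatch is one source of the small
late drift discussed below.  Plasticity runs only while examples are
presented; spontaneous and inference activity never triggers updates.

## The generative model and the weight mapping

A module with inputs x (cardinalities M_i), output z (values 1..L) and
J^l hidden neurons per output value implicitly defines

    p(a, z, x; θ) ∝ [z = l(a)] · exp(b̂_a + Σ_i ŵ_{i,x_i,a})

over a one-hot hidden variable a (plus a null component for "no recent
spike").  The natural parameters are mapped from the network as
**ŵ = T(w + w⁻), b̂ = T(b + b⁻)**.  At T = 1 this is the plain affine
shift of the analytic treatment; for the T-scaled potentiation used in
the study fixtures it is the unique affine map under which the rule's
fixed points w = −w⁻ + ln(p)/T land at ŵ = ln p, i.e. at
log-probabilities of the generating distribution — with the unscaled
map the learned model would be tempered by 1/T and could not reproduce
the generating tables.  A corollary worth knowing: with T < 1 the
*network dynamics* (which exponentiate u = θ̂/T + const) sample a
sharpened version of the analytic model, which makes sampled
conditionals slightly crisper than the enumerated ones.

Fixed entries: zero-value likelihood parameters are pinned at −V
(V = 50; e^(−V) ≈ 2·10⁻²²), while the null component carries b̂₀ =
T·b⁻ and per-input T·w⁻, matching the network's output-rate identity
ρ_l = (1/τ)·p(z=l|x)/p(z=0|x) exactly at T = 1.  Consequently the
model mass on zero-value states is not exactly zero: it is of order
exp(T(b⁻ + I·w⁻)) — a few percent in the trained fixtures — and the
reported model tables are the raw enumerated values, not renormalised
over non-zero states.  All enumeration uses log-sum-exp; modules are
guarded to ≤ 10⁶ states.  Normalisation residuals c₀ and c_ijl sum
over learnable entries only (l ≠ 0, m ≠ 0).

The analytic layer also provides the exact EM iteration
(b̂ = ln p*(a), ŵ = ln p*(x|a)) as a learning-dynamics oracle, the
mean update h̄(θ) = E[Δθ] over the complete-data distribution (whose
dot products with the residual gradients are −c₀ and −p*(a)·c_ijl —
identities asserted to 10⁻⁸), and a point-mass construction that sets
module parameters directly from a target table (one hidden component
per input assignment, likelihoods 1 − ε(M−1) / ε).  The construction
realises the computability condition for sampling networks and serves
as the oracle for the sampler tests.  Constructed networks apply a
uniform excitability shift (default −6) to every hidden bias: it
rescales each module's intensities by a common factor — the sampled
conditionals are unchanged — but spreads the otherwise lock-stepped
release races by tens of microseconds, restoring the asynchronous
updating the sampling theory assumes.  Without it, all modules of a
raw construction fire in synchronous 15 ms rounds and resample exactly
when their inputs' half-open windows expire, which biases the
stationary distribution toward flatness.

## Module and network construction

Wiring constants (defaults, used by both studies): relay weight
w_pp = 20, excitation of the 5-neuron inhibitory pool w_e2i = 80,
inhibition w_i2e = −7, biases of principal/inhibitory relay neurons
−10.  Initial plastic weights are Gaussian (mean w_max/3, or 3.0 in
the association study; SD 0.1) redrawn until inside the clip bounds;
initial biases Gaussian(5, 0.1) — hidden neurons start highly
excitable so every subpopulation fires on early examples.  The bias
offset per module is

    b⁻ = 2.5·T·(−|B| ln 0.2 − Σ_i ln(M_i + 1) + ln 0.02)

with |B| the number of input variables, counter-balancing the average
total input a hidden neuron receives; the prefactor is 2.5·T (for the
association study, T = 0.4, this equals 1), which keeps every bias
fixed point strictly inside [b_min, b_max] — a 2.5/T reading would
push them against the upper clip and flatten the learned priors.

In composite networks the output population of module k *is* the input
population of every module whose variable has y^k in its input set —
shared neuron ids, no copies.  Example presentation: coding principal
neurons receive +30, non-coding −30, and hidden neurons outside the
subpopulation of the presented output value −80, for 100 ms per
example, back to back with no gaps.  The ~τ of residual-PSP
contamination at each example onset is accepted, not corrected.

## Decoding, sampling, inference

A spike of the neuron coding y^k = l sets the variable to l for τ,
after which it falls back to 0; later spikes win.  Stationary
distributions are time-weighted histograms of fully non-zero decoded
states (the dwell fraction of zero-containing states is reported
separately — around 1 % in trained networks, concentrated in the
per-variable gaps between a value's expiry and the next relay spike).
Stationary runs start from a uniformly random state injected as 2 ms
current pulses and use a burn-in (default 20 s for long runs, 0 for
400 ms inference snapshots, which rely on the random initial state
instead).  Inference clamps evidence neurons with the training
amplitudes (±30) and applies no hidden-population gating; posteriors
are reported both as dwell fractions and as output-spike-count shares.
Rate read-outs use the causal normalised alpha kernel
K(t) = (t/τ_K²)e^(−t/τ_K), τ_K = 0.1 s.

## Study conditions and problem sizes

Both reference studies train for 1200 s of simulated time (12 000
examples), checkpoint every 60 s, and use the printed schedules:
synaptic rate linear 0.002 → 0.0006 over the first 600 s then 0; bias
rate 0.01 then 0.02.  T = 0.4 / w_max = 5 in the association study;
T = 0.58 and w_max = 4 (modules y1–y3) / 2 (y4) in the explaining-away
study.  The test suite runs the association study across five seeds
and the network study once, with ten 400-ms inference snapshots per
evidence condition; the acceptance script reports the median of five
association-study seeds and of three network trainings, each with a
300 s stationary run.  The sampler oracle uses a three-variable joint
and a single 1220 s run evaluated on nested windows.  These sizes are
the package's own reproduction scale; the underlying protocol is
unchanged.

## What the synthetic data does and does not show

All training data are i.i.d. draws from the known target tables, the
study conditions the framework is defined for.  Passing tests
therefore show that the *mechanism* works — STDP plus intrinsic
plasticity implement stochastic EM on these architectures, and the
learned networks sample and infer correctly — not that the approach is
robust to non-stationary inputs, correlated example streams,
mis-specified blankets, or biological parameter ranges beyond those
studied here.

## Known limitations

* **Clip-floor bias.**  With w_min = 0 the smallest learnable
  likelihood is e^(T·w⁻) (0.2 in the association study), so off-mode
  cells of sharply peaked targets are systematically overestimated;
  the learned association-study joint stabilises around total
  variation ≈ 0.09 from its generating table, dominated by exactly
  those cells, while the modes and the conditional structure are
  recovered well.  This is a property of the rule's fixed points under
  the study's clip bounds, not a simulation artifact.
* **Late KL drift.**  After the synaptic phase ends (η = 0) the bias
  rule keeps adapting with η′ = 0.02, and with alpha-shaped EPSPs the
  objective can creep up by a few hundredths of a nat over the second
  600 s — the same slight increase the theory's rectangular-PSP
  idealisation does not show.
* **Tempered sampling at T < 1.**  See above; sampled conditionals are
  sharper than enumerated ones, which helps decision-like read-outs
  and slightly distorts calibrated probabilities.
* **Snapshot inference is noisy.**  A single 400 ms inference run from
  a random initial state carries only a handful of switches between
  the competing-cause modes (the two-cause joint switches roughly
  every hundred milliseconds), so individual snapshots can misorder
  the weaker posterior flip in the evidence-flip comparison even
  though the shading–shape posterior drop is reproduced essentially
  always; longer runs tighten the estimates at the cost of leaving the
  single-glance regime.
* The inhibitory pool makes the WTA constraint statistical, not hard:
  a small fraction (< 1 %) of hidden-spike pairs fall within one
  coding window.
* No synaptic delays, no conductance-based dynamics, no growth of
  hidden populations; graphical models must be small enough to
  enumerate for the analytic layer (the simulator itself has no such
  limit).
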