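# Methods

## Model

Three cortical areas of the dorsal visual stream (v1, v2, v5) are each
modelled as a four-population neural mass: pyramidal cells (PY),
excitatory interneurons (eIN), slow inhibitory interneurons (sIN) and
fast inhibitory interneurons (fIN), with PY→{eIN, sIN, fIN} excitation,
{sIN, fIN}→PY inhibition, eIN→PY excitation and mutual sIN↔fIN
inhibition.  Every synaptic pathway is a linear second-order channel
ẏ = x, ẋ = H·a·u − 2a·x − a²·y (gain H in mV, rate constant a in s⁻¹)
driven by a firing rate u, and rates derive from summed potentials via
the odd sigmoid S(v) = 2e₀/(1+e^(−r·v)) − e₀, so rates live in
(−e₀, +e₀) around a zero resting state.  The 36-dimensional state
holds the (y, x) pairs of the 12 population channels and of the 6
long-projection channels.

Long projections carry the delayed pyramidal rate of the source area,
k_ij·z_pj(t−T), through an excitatory channel of the *target* area
(its Hₑ, aₑ).  Ascending projections (k₁₂, k₁₅, k₂₅) add to the eIN
input of the target; descending ones (k₂₁, k₅₁, k₅₂) add to both the
PY membrane sum and the fIN input.  v5, the top of this hierarchy,
receives no descending input.

### Parameters

Intra-area connection weights (all dimensionless, fractions of the
PY→eIN weight) and the basal constants are taken verbatim from the
published tables of this model family; e.g. area v1 has Cpe1 = 65,
Cep1 = 52, Hf1 = 173.1 mV, af1 = 790 s⁻¹.  Two points needed a
decision:

* **Units of the rate constants.** The source table labels a as
  "ms⁻¹", but values of 20–790 are only dynamically consistent as s⁻¹
  (as ms⁻¹ all rhythms would sit in the kHz range).  The whole system
  runs in SI seconds with T = 0.010 s.
* **Exogenous drive.** Each area's eIN channel receives
  (z_e + p_i/c_ep), with p_i Gaussian.  The published variance
  σ² = 60 is kept; the published mean m = 100 is **not** the default.
  With the zero-centred odd sigmoid above, a constant drive of that
  size pushes every area ~5 mV into sigmoid saturation, where the
  loop gains are too small to sustain any of the reported rhythms (v5
  in particular shows no alpha resonance at any noise level;
  fixed-point and eigenvalue analysis confirm this).  A zero-mean
  drive — the natural symmetric convention for a sigmoid that is odd
  around zero — restores the reported gamma/beta/alpha intrinsic
  rhythms and all qualitative coupling phenomenology.  The default is
  therefore m = 0 (`m1`, `m2`, `m5` in the config remain overridable).
  The value 100 matches the input convention of the ancestor models
  whose sigmoid is non-negative and centred near 6 mV, which is likely
  how it entered the table.  Relatedly, the tabulated sigmoid centre
  s0 = 6 mV appears in no printed equation of this model; it is stored
  in the config for fidelity but unused.

Noise enters as one independent N(m, σ²) draw per Euler step per area
(`noise_scaling="per_step"`), matching the common fixed-step practice
for this model family; the alternative Wiener-increment convention
(std scaled by 1/√dt) is available as `noise_scaling="sqrt_dt"` but
pushes the uncoupled v5 peak out of the alpha band, so it is not the
default.  Each area's stream is seeded from (seed, area index), making
runs reproducible and areas independent.

## Integration

Explicit fixed-step Euler with dt = 2 ms, exactly as in the published
protocol; the delay T must be an integer number of steps (10 ms → 5).
Delayed pyramidal rates come from a per-step history; times before 0
read zero, which equals the resting rate since S(0) = 0 and is
forgotten with the discarded transient.  State starts at zero; runs
last 600 s of which the first 30 s are dropped.  The integrator is a
numba-compiled kernel; a pure-numpy loop over the reference
right-hand side (`model.rhs`) is kept as an independent oracle and the
two agree to round-off in the tests.  dt·a_f reaches 1.58 for v1's
fast-inhibitory channel, inside the Euler stability region (< 2) but
coarsely resolved — this is a property of the published protocol that
the package reproduces rather than corrects; convergence tests
therefore compare refinements of dt against each other, not against
dt = 2 ms.

Non-finite states abort the run with the index of the first offending
step.  Identical seeds give bit-identical results and output files.

## Spectral analysis

Channels are band-passed 3–60 Hz with a zero-phase (forward–backward)
order-5 Butterworth before any estimation.  PSDs use Welch's method
with a Hamming window and 50 % overlap; the default 4 s segment gives
0.25 Hz resolution at the 500 Hz sampling rate, the grid on which all
reported peaks lie.  Coherence is |P_xy|²/(P_xx·P_yy) from the same
Welch scheme, computed per run and averaged across the ensemble
(pooling the cross- and auto-spectra across runs before the ratio is
available as `coherence_method="pooled"`; for these ensembles the two
differ negligibly because the transfer phase is stable across runs).
Band summaries are inclusive-endpoint means or maxima on the grid, and
peak picking breaks ties toward the lower frequency.  PLV and PPC use
analytic-signal phases of band-passed channels; PPC is the unbiased
estimator (|Σe^{iΔφ}|² − n)/(n(n−1)), with zero expectation for
independent phases.

## Experiments

The canonical projection-loss experiments fix all non-lesioned
projections at 10 and sweep one: k₂₁ from 20→0 (read-out: mean v2–v1
coherence over 24.5–25.25 Hz), k₅₂ from 25→0 (v5–v2, 11.5–12 Hz; the
source figure caption says 30→0 but the text 25→0, and 25 is used),
and k₂₅ from 50→0 (v2–v5, 25.75–26.25 Hz).  The uncoupled baseline
(all k = 0) exposes the intrinsic rhythms.  Default grids use step 1
over these ranges and always include the five published panel values.

## What the simulations do and do not show

All data are generated by the model itself; there is no fitting to
clinical EEG.  The Gaussian drive emulates unmodelled afferents, not
measurement noise; real EEG adds volume conduction, non-stationarity
and measurement artefacts that this pipeline does not emulate, so
passing tests validate the model's internal phenomenology, not
clinical effect sizes.

With the conventions above, the package reproduces the qualitative
published phenomenology in full: intrinsic gamma/beta/alpha peaks for
v1/v2/v5; near-perfect beta coherence under a strong descending v2→v1
projection that collapses as the projection is lost; alpha coherence
between v5 and v2 that falls with k₅₂; beta coherence between v2 and
v5 that falls with k₂₅; and declining coherence when the secondary
projections k₅₁ and k₁₅ are removed.  Known quantitative deviations
(the published code's exact noise handling is not recoverable, and the
printed noise mean contradicts the printed spectra, so some offset is
expected):

* The coupled network's beta rhythm peaks at ~23.5 Hz instead of the
  reported 24.75 Hz (≈5 % low); the v5-driven alpha coherence peaks at
  12.0 rather than 11.75 Hz.
* Residual coherence floors differ: with k₂₁ = 0 the 24.5–25.25 Hz
  band mean settles near 0.27 (reported: below 0.1), and with
  k₂₅ = 5 the beta coherence peak is ~0.41 (reported ≈0.7).
* The k₅₂ = 25 alpha coherence peak reaches ~0.86 (reported ≈1), and
  k₅₂ = 15 gives ~0.69 (reported ≈0.8).
* Because the coupled rhythm frequency drifts ~1 Hz as a projection
  weakens, the fixed read-out bands produce locally non-monotone
  coherence-vs-k curves (e.g. a bump at k₂₁ = 5); the plateau and the
  final collapse reproduce.
* The ascending v1→v2 projection k₁₂ has almost no coherence leverage
  at the published gains: v2's eIN channel (aₑ₂ = 85 s⁻¹) strongly
  attenuates v1's gamma band and the parallel descending k₂₁ path
  dominates the v1–v2 relation, so no declining-coherence claim is
  made for it.

The acceptance tests and `scripts/acceptance.py` run the full
published protocol (ensembles of 50 × 600 s; roughly ten seconds per
condition with the compiled kernel).  The examples use 10 × 150 s for
quick turnaround; peak band membership is stable at that scale but
argmax-based peak locations can jitter by one or two 0.25 Hz bins.
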