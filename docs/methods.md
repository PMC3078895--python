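# Methods

This note records what `hosbeat` computes, the parameter values it ships
with and why, what the synthetic generator does and does not establish, and
the numerical decisions that matter for reproducing its outputs.

## Signal model and assumptions

A beat is 201 samples at 360 Hz in millivolts, R-peak aligned at index 100
(±100 samples ≈ ±278 ms around the R wave). The classifier assumes this
alignment has already been done by an upstream QRS detector; it does no
detection or resampling of its own. Beats are treated as independent —
rhythm context (RR intervals, preceding beats) is deliberately outside the
model, which is a morphological classifier only.

## Cumulant features

Each beat is mean-centered, then the diagonal slices of its 2nd-, 3rd- and
4th-order cumulants are estimated at lags τ = −100…100 with the biased
(1/L) normalisation:

- c₂(τ) = (1/L) Σᵢ xᵢ xᵢ₊τ
- c₃(τ, τ) = (1/L) Σᵢ xᵢ xᵢ₊τ²
- c₄(τ, τ, τ) = (1/L) Σᵢ xᵢ xᵢ₊τ³ − 3 c₂(τ) c₂(0)

Sums run over the overlap of the two index ranges; there is no wraparound
or zero padding. The biased estimator keeps the variance of long-lag
estimates bounded at the cost of a known shrinkage toward zero at large
|τ|; since every beat is treated identically the shrinkage is a fixed
feature transform, not a bias in the comparison between classes.

Properties relied on: invariance to additive constants (via centering, see
"Exact amplitude-shift invariance" below); c₂ is exactly even in τ. The
3rd- and 4th-order diagonal slices are *not* symmetric in τ for
finite-sample estimates — their asymmetry carries class information and is
kept.

## Hermite models

Each 201-point slice is approximated by N orthonormal Hermite basis
functions φₙ(t, σ) evaluated on the integer grid t = −100…100. The basis
is built by the stable normalised recursion
φₙ = √(2/n)·(t/σ)·φₙ₋₁ − √((n−1)/n)·φₙ₋₂, which avoids the overflow of
the explicit Hₙ·n!-normalisation form at high orders. Coefficients are the
least-squares solution of the 201-equation, N-unknown system via SVD
pseudo-inverse (`numpy.linalg.lstsq`, `rcond=1e-12`); model quality is the
normalised error E = ‖x − Φa‖² / ‖x‖².

**Default order N = 26.** This keeps the system strongly overdetermined
(201 equations, 26 unknowns) while reconstructing synthetic cumulant
slices with E well below 10⁻². The feature vector per cumulant order is
the 26 coefficients (σ can optionally be appended via
`include_sigma=True`).

**Discrete orthonormality window.** On the ±100-sample grid the Gram
matrix ΦᵀΦ is the identity to better than 10⁻⁹ for σ ∈ [4, 10] and
N ≤ 30. Outside that window it degrades on both sides: for large σ the
basis functions' support (the classical turning point sits near σ√(2N+1))
extends past the grid and tails are truncated; for σ ≲ 3 the highest-order
oscillations alias on the unit sample spacing. The least-squares fit does
not require orthonormality — the pseudo-inverse handles an ill-conditioned
Φ — but interpretability of coefficients as projections only holds inside
the window.

## Width optimisation (genetic algorithm)

σ is optimised per signal by a small elitist GA:

| parameter | value |
|---|---|
| population | 10 |
| parents kept | 2 (lowest E) |
| offspring | 8, affine crossover σ = ασ₁ + (1−α)σ₂, α ∈ {−0.25, 0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.25} |
| mutation | multiplicative, σ ← σ·exp(𝒩(0, 0.1²)), probability 0.9 |
| bounds | σ ∈ [2, 60] samples (clipped) |
| stopping | 30 generations, or best-E improvement < 10⁻⁶ for 5 consecutive generations |

The α grid spans interpolation and mild extrapolation between the two
parents so the eight offspring cover a bracket around them; the
multiplicative mutation explores σ on a log scale, matching the roughly
scale-free effect of width on fit error. On synthetic cumulant slices the
GA lands within 5% relative error of a 1000-point grid search over the
same bounds (verified in the test suite), at roughly 1/6 the number of
error evaluations.

GA randomness is derived from the classifier's `random_state` and the
cumulant order only — `seed = (random_state·1 000 003 + 7919·order)
mod 2³¹` — never from the beat's content or its position in a batch, so a
beat's features do not depend on what other beats it is processed with.

## Classification and fusion

Each cumulant order has its own bank of training coefficient vectors. A
test beat gets one label per order by 1-nearest-neighbour under squared
Euclidean distance (ties broken toward the lowest training index, making
prediction deterministic). The three labels are fused by majority vote;
when all three disagree the 3rd-order label is used, on the grounds that
the skewness slice is the most class-discriminative single statistic for
these morphologies. `SignalHermite1NN` applies the identical Hermite +
1-NN machinery to the raw centered waveform and serves as the ablation
baseline isolating the contribution of the cumulant stage.

## Evaluation

Metrics are one-vs-rest: Se = 100·TP/(TP+FN), Sp = 100·TN/(TN+FP) per
class, pooled (micro-averaged over summed counts) values, and macro
sensitivity (unweighted mean of per-class Se). Reported values are rounded
half-away-from-zero to two decimals. The stratified split assigns each
class ⌊f·n + 0.5⌋ beats to training. The package ships, as plain data
constants (`hosbeat.reference`), previously published per-class split
totals and confusion counts from a five-class MIT-BIH benchmark of this
method; the evaluation code reproduces those tables' arithmetic to the
printed precision. Note the published tables mix rounding with truncation
to two decimals (e.g. an average sensitivity of 98.6652 printed as 98.66),
so agreement is asserted to the printed precision rather than as exact
two-decimal rounding everywhere.

## Synthetic generator — scope

The generator draws each beat from a per-class template of Gaussian bumps
(P/Q/R/S/T-like components) with independent per-component amplitude
jitter (6% relative, matching the spread of R amplitudes in annotated
recordings), width jitter (4%), and a baseline offset draw (0.03 mV). The
five default templates are clinically motivated caricatures — e.g. the PVC
template is wide and bimodal without a P wave, the APC template has an
inverted premature P and reduced R — and are separated by 6.8× the RMS
jitter scale, so the synthetic task is *easy by construction*.

Consequently the synthetic benchmark establishes correctness and the
claimed invariance/robustness mechanisms, not clinical performance: a
passing test suite shows the pipeline computes what it says and that the
cumulant stage degrades more gracefully than the raw-signal baseline under
the tested perturbations *on these morphologies*. It says nothing about
sensitivity on real recordings, inter-patient variation, electrode
artefacts, or class imbalance beyond what the published reference tables
record.

## Numerical design decisions

**Exact amplitude-shift invariance.** A constant offset added to a beat is
stored in a separate `baseline` scalar rather than folded into the float64
samples. Mean-centering then cancels the offset symbolically, so cumulant
values, Hermite coefficients and predictions after an amplitude shift are
*bit-identical* to the unshifted ones — a property that eager floating-point
addition cannot provide (adding and subtracting 0.1 perturbs the last few
ulps). Code that needs the literal shifted waveform uses the `samples`
property, which materialises `waveform + baseline`.

**Determinism.** Every random draw (generator, splits, GA, noise) flows
from explicit integer seeds; repeated runs with the same seeds are
bit-identical. Per-beat noise seeds are derived as `seed + ordinal` so a
beat's perturbation does not depend on batch composition.

**Benchmark problem size.** The in-repo benchmark uses 200 beats per class
(1000 total), a 60/40 stratified split, and order-26 models — large enough
that macro sensitivities are stable to ~1 percentage point across seeds,
small enough to run in a few minutes on one CPU.

## Known limitations

- Rhythm-dependent classes (e.g. distinguishing APC from N relies partly
  on prematurity in real ECG) are modelled purely morphologically here.
- The noise-robustness comparison against the raw-signal baseline at noise
  variance 0.05 mV² is seed-dependent in magnitude: the fused cumulant
  model's sensitivity drop is smaller than the baseline's under the
  benchmark conditions used in the test suite, but the margin is modest
  and can invert for some generator seeds. The package does not claim a
  uniform advantage at this noise level.
- The 4th-order slice is the noisiest feature (higher-order moments have
  higher estimator variance); at small training sizes its 1-NN vote can
  lag the 2nd/3rd-order votes, which the fusion rule partly absorbs.
- No empirical result is asserted beyond what the test suite and
  `scripts/acceptance.py` actually compute; in particular, the published
  reference tables are reproduced arithmetically, not re-derived from
  recordings.
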