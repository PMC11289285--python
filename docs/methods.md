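# Methods

This note documents the models, estimators and numerical choices behind
`placecode`, and what the synthetic sessions do and do not establish about
real recordings.

## Session model and conventions

A session is a set of per-frame arrays: ΔF/F (neurons × frames), optional
raw fluorescence and deconvolved rates, frame times, and belt position.
Positions are centimetres on the half-open circular interval `[0, L)` with
`L = 180 cm` (four 45 cm textures); the angle is `θ = 2πx/L`. This single
convention is used by every module. Telemetry (encoder ticks, RFID tag
reads) is resampled to frame times by last observation carried forward —
the encoder is a counter, and interpolating it would invent motion.

**Position reconstruction.** The running estimate is the cumulative sum of
encoder increments. At each RFID event the estimate snaps to the tag's
registered belt position, choosing the lap count that minimises the
correction; this bounds accumulated drift by (relative drift) × (inter-tag
spacing), e.g. < 2.25 cm for a 5% encoder scale error with tags every
45 cm. The correction is a hard reset by default; a linear
back-distribution over the samples since the previous tag is available
(`drift_correction="linear"`). With noise-free ticks the reconstruction is
exact to 1e−9 cm.

**ΔF/F.** `(F − r·F_neu − F0)/F0` with neuropil coefficient `r = 0.7`
(0 when no neuropil trace is supplied) and `F0` a centred rolling
10th-percentile baseline over 60 s, floored at a small positive constant.
A percentile baseline sits slightly below the true quiescent level on
noisy traces (≈ 1.3 noise sd for the 10th percentile), which inflates ΔF/F
by the same small factor; this is the standard trade-off of
percentile baselines and is irrelevant to any within-pipeline comparison.

## Transient detection and activity

ΔF/F is filtered with a third-order zero-phase Butterworth low-pass
(default cutoff 2 Hz at 15 frames/s — wide enough to preserve
red-indicator kinetics). A transient starts where the filtered trace rises
`2σ` above a rolling-mean baseline and ends below `0.5σ`. Detected
transients are excluded, the baseline and σ re-estimated from the
remaining frames, and detection repeated — 3 iterations — so large events
do not inflate the noise estimate. σ shrinks essentially monotonically
across iterations (tiny re-estimation jitter below 0.1% is possible).

Defaults chosen where the procedure needs a concrete value:

| parameter | default | unit | rationale |
|---|---|---|---|
| rolling-mean window | 30 | s | long vs. ~1 s transient timescale |
| low-pass cutoff | 2 | Hz | preserves indicator kinetics at 15 Hz |
| minimum duration | 0.2 | s (3 frames) | suppresses single-frame noise crossings |
| start / end thresholds | 2 / 0.5 | σ | detection rule |

The raw 2σ/0.5σ rule on white noise admits a few short false runs per
thousand frames (the rate is scale-invariant in σ); the minimum-duration
rule is what controls them. Activity is the summed significant-transient
ΔF/F (from the filtered trace; a toggle selects the unfiltered one)
converted to ΔF/F·s and divided by the distance travelled.

## Tuning index

Rates come from a nonnegative first-order autoregressive inversion of the
calcium kernel: with `γ = exp(−1/(f_r·τ))`, the event estimate is
`max(0, c_t − γc_{t−1})`, scaled to events/s. The operator is positively
homogeneous, so indices are invariant to trace rescaling. Rates below 2
noise standard deviations are zeroed; the rate-noise σ is the transient
detector's final σ mapped through the inversion's white-noise gain
`√(1+γ²)·f_r` (a robust MAD estimate is the fallback). Frames slower than
0.5 cm/s are excluded from occupancy and averaging (rare on a
treadmill-driven belt).

The tuning vector over 100 bins is the mean resultant
`r = Σᵦ wᵦe^{iθᵦ}/Σᵦ wᵦ` of the occupancy-normalised thresholded rates;
the index `|r|` is bounded in [0, 1] and equals `I₁(k)/I₀(k)` for a pure
von Mises profile of concentration k. The alternative normalisation
(occupancy only, no unit-sum division) is unbounded and incomparable
across cells; it remains available via `normalization="occupancy"`.

## Von Mises fitting

The 20-bin lap-averaged ΔF/F curve is fitted with
`f(θ) = B + A·e^{k(cosθ−φ)−k}` by bounded least squares (`A ≥ 0`,
`0 ≤ k ≤ 50`; beyond k = 50 the peak is narrower than one bin). Multiple
starts (circular-mean φ, curve-peak φ, flat, narrow) guard against local
minima; ties break by lowest SSE then lowest k; an analytic Jacobian keeps
fits fast. A flat curve returns `A = 0`, `B = mean` with a degenerate flag
since k and φ are unidentifiable.

Cross-validated R² fits the model to the per-bin means of 75% of the lap
samples within each bin and scores `1 − ss_res/ss_tot` on the held-out
25%, averaged over 10 deterministic seeded splits. `ss_tot` is taken about
the held-out mean (the full-data-mean variant is a toggle). The reported
value is clipped to [0, 1] — negative cross-validated R² means "worse than
the constant model" and is retained unclipped for diagnostics. Cells with
R² > 0.5 are "well fitted". Peak width is `V = 1 − I₁(k)/I₀(k)`, computed
with exponentially scaled Bessel functions for stability at large k.

Fits on raw ΔF/F curves inherit a bias from the calcium kernel: the
exponential tail smears activity along the running direction, shifting the
apparent peak by roughly (speed × τ ≈ 7 cm ≈ 14°) and widening it.
Parameter-recovery tests therefore fit curves built from deconvolved
rates, where the kernel is undone; ΔF/F fits are kept for amplitude and
goodness-of-fit comparisons, where the smearing is common to all groups.

## Decoding and Fisher information

The decoder is multinomial logistic regression on per-frame ΔF/F over 20
position bins, 10 random stratified 75/25 splits (stratification
guarantees every bin in every training fold). L2 strength is a fixed
configurable constant (`C = 1`): a nested per-fold search would multiply
cost several-fold while none of the reported quantities is sensitive to it
(chance level and separable data are regularisation-independent, and group
contrasts share a common C). Accuracy on label-shuffled data sits at the
1/20 = 5% chance level. When populations differ in size across sessions,
a fixed-size neuron subsample (default 42, 10 draws averaged) equalises
them; sessions below the threshold are flagged, never padded.

For each circularly adjacent bin pair, lap responses project onto the
difference of the two classes' decoder weight vectors, giving a 1-D signal
with `d'² = (μ₁−μ₂)²/(½(s₁²+s₂²))` — linear Fisher information for that
9 cm step. Small-sample bias is removed with

    d'²_bc = d'²_naive · (2T − N − 3)/(2T − 2) − 2N/T

with T laps per bin and N estimated dimensions. N = 1 throughout: the
population signal is one-dimensional after projection onto fixed decoder
weights, and single-cell FI is one-dimensional by construction. Under the
null this makes the estimator exactly unbiased (`E[naive] =
(Δμ²/σ² + 2/T)·(2T−2)/(2T−4)` for Gaussian data, so the correction cancels
the bias identically), at the cost of slightly negative values on
uninformative data — reported as-is, never clipped. Pairs with zero pooled
variance are skipped with a warning.

Information per cm² is `J = d'²/δs²` with `δs = 9 cm`. The discrimination
threshold assumes the local-linear Gaussian model `d'(δ) = δ√J` and an
equal-prior single-interval ideal observer, `PC(δ) = Φ(d'/2)`, giving
`δ* = 2Φ⁻¹(criterion)/√J` at the default 70% criterion. The 2AFC
convention `Φ(d'/√2)` is available via `observer="2afc"`; the
single-interval form matches a present/absent judgement at one location
and is the default.

The noise-correlation surrogate permutes lap order independently per
neuron within each position bin: per-neuron per-bin marginals — hence all
tuning curves — are preserved exactly (bitwise multiset equality), while
cross-neuron within-bin covariance is destroyed in expectation; residual
correlations fall below the 2/√T permutation bound.

## Nested bootstrap

Cell-level metrics pooled across animals violate i.i.d. assumptions, so
group differences are tested with a two-level bootstrap: animals from both
conditions form one pool; each replicate fills each condition's original
animal slots with animals drawn (with replacement) from the pool, then
draws each slot's original number of cell values within the drawn animal;
the difference of pseudo-condition means forms the null. The two-sided
p-value is the fraction of replicates at least as extreme as the observed
difference of means, floored at `1/(n_boot+1)`. Default
`n_boot = 100 000`; calibration experiments use 2000.

Drawing a *new* animal for every value (a plausible alternative reading of
"the animal and data value were sampled") collapses the two levels into
i.i.d. sampling from the pooled mixture; measured on hierarchical nulls
(5 animals/group, 50 cells each, between-animal sd 0.5, within sd 1.0) it
rejects ~25% of the time at α = 0.05 and cannot be called nesting-aware.
The within-animal scheme measures 0.054 under the same null with power
0.99 against a shift of 3 between-animal sds. The flat variant is kept
behind `value_resampling="pooled"` for sensitivity analysis only. The
hierarchical scheme is mildly conservative when within-animal standard
error is comparable to between-animal sd (the bootstrap adds both), and
slightly anti-conservative when between-animal variance carries essentially
all of it; with ≥ ~50 cells per animal it is close to nominal. Note also
that because the null pools animals across conditions, its spread grows
with the true effect; with very few animals per group, p-values bottom out
at a combinatorial floor regardless of effect size — group comparisons
here use 5–9 animals per condition, where the floor is well below 0.05.

Bonferroni correction is `p_adj = min(1, m·p)`. The behavioural
discrimination index is `(freeze_A − freeze_B)/(freeze_A + freeze_B)`.
Standard tests (Mann-Whitney, ANOVA variants) are delegated to scipy and
are not re-derived here.

## Synthetic sessions: what they emulate

The generator reproduces the statistical structure the analysis assumes:

- **Trajectory** — speed fluctuates slowly (AR(1), ~2 s correlation time,
  sd 23 cm/min) around 421 cm/min; encoder ticks can carry scale error and
  per-sample noise; RFID events fire at true texture-boundary crossings.
  Sessions default to 21 laps ≈ 9 min at 15 frames/s.
- **Rates** — `λᵢ(x) = g·(Bᵢ + Aᵢe^{kᵢ(cosθ−φᵢ)−kᵢ})` with a tuned
  fraction (default 0.5) drawing `A ∈ [0.5, 1.5] events/s`,
  `k ∈ [2, 8]`, φ uniform; untuned cells have `A = 0`. Baselines
  `B ∈ [0.02, 0.1] events/s` keep activity sparse. The gain `g` scales all
  rates before the noise stage.
- **Spiking and calcium** — Poisson counts per frame (the simplest process
  consistent with sparse DG activity); single-exponential kernel,
  `τ = 1 s`, instantaneous rise (keeps deconvolution-based recovery tests
  analytic); additive Gaussian ΔF/F noise, sd 0.05.
- **Shared gain** — one global log-normal AR(1) multiplier (mean 1,
  sd 0.2, 5 s correlation time) multiplies every neuron's rate, producing
  small positive noise correlations with a single parameter. No
  measurement of the real magnitude of this variability exists in the
  source data, so the default is a free, exposed choice.
- **Determinism** — every stochastic stage draws from its own named
  substream of the root seed; identical config + seed regenerates the
  session bit for bit, and `apply_gain` re-simulates with the same seed so
  only the rate scale changes.

What passing tests on synthetic data do **not** show: real DG sessions
have non-Poisson burstiness, indicator nonlinearity, neuropil
contamination, drift and motion artefacts, remapping, and behavioural
covariates (speed/direction coding) that the generator omits. Synthetic
results validate the *estimators* — their calibration, invariances and
effect directions — not any biological claim.

## Problem sizes used in the shipped experiments

Calibration and acceptance experiments run at deliberately modest sizes
chosen so the full suite stays interactive: sessions of 40–80 neurons and
12–25 laps, 200 replicate Gaussian datasets at T = 200 for estimator
accuracy, 1000 nulls at T = 20 for bias, 500 hierarchical null simulations
at 2000 bootstrap replicates for test size, and 9 simulated animals per
condition for the gain contrast. All scale knobs are plain function
arguments; nothing in the implementation depends on these sizes.

## Known limitations

- The percentile ΔF/F baseline is biased low on high-noise traces (see
  above); activity comparisons across very different noise levels should
  use matched acquisition parameters.
- Single-cell FI uses adjacent-bin pairs only (local discrimination);
  non-adjacent pairings would mix tuning-curve global shape into the
  estimate and are deliberately out of scope.
- The decoder reports fraction correct, not distance-weighted error; at
  high accuracy the two diverge.
- `apply_gain` requires a synthetic session (it re-simulates); for real
  data, gain is a hypothesis to be tested via the amplitude and FI
  contrasts, not an operation.
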