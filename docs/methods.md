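# Methods

`surrqa` tests short beat-interval (NN/RR) series for nonlinear dynamics by
surrogate-data hypothesis testing with recurrence-quantification indices as
the discriminative statistics. This note records the models, the numerical
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## The hypothesis test

For a series `x` and a statistic `S`, an ensemble of `n` surrogates realizes
a linear null hypothesis. The two-sided min-tail Monte-Carlo p-value is

    p = (1 + #{surrogates with S at least as extreme as S(x), nearer tail}) / (n + 1)

With the default `n = 99` the attainable floor is `p = 0.01`, reached when
the original lies strictly outside the surrogate range; the null is rejected
at `p < 0.05`. Ties count as "at least as extreme" (the conservative
direction), and p-values are invariant to the order of the surrogate list.
Each RQA index is tested separately without multiplicity correction across
indices; rejection-rate tables aggregate per index across records.

## Surrogate generators

**IAAFT** (iterative amplitude-adjusted Fourier transform) realizes the null
of a *stationary* linear Gaussian process observed through a static
invertible transform. Starting from a seeded random permutation, the
iteration alternates (a) replacing Fourier amplitudes with the original's
while keeping current phases and (b) rank-remapping values onto the
original's sorted amplitudes, stopping when the rank ordering repeats
(typically 15–30 iterations at N = 300, residual spectral discrepancy
~1%). The final step is the rank remap, so the surrogate's value multiset
equals the original's bitwise.

**PWIAAFT** (pinned-wavelet IAAFT) relaxes stationarity. The series is
decomposed with a MODWT (maximal-overlap discrete wavelet transform;
Daubechies least-asymmetric order-8 filters, circular boundary,
`floor(log2 N) − 2` levels by default). Detail coefficients are pinned —
held at their original time positions — according to `rho`, each scale's
remaining coefficients are IAAFT-randomized among themselves with pinned
positions re-imposed every iteration, and the deepest-level smooth
coefficients are kept fixed (trend preservation). Because MODWT scale bands
overlap, summing independently randomized scales whitens the composite
spectrum (~25% amplitude discrepancy); the reconstruction therefore enters
an outer loop that alternates full-series IAAFT steps with re-imposition of
the pinned/smooth wavelet content (max 20 rounds, final step the rank
remap). This restores spectral fidelity to ~1–2% while keeping the pinned
features in place.

**Pinning rule.** `rho` is the fraction of total detail-coefficient energy
held fixed: the largest-magnitude coefficients across all detail scales are
pinned, fewest first, until they carry `rho` of the energy. `rho = 0` pins
nothing (pure wavelet-IAAFT) and `rho = 1` reproduces the original exactly.
An alternative per-scale amplitude rule (`pin_rule="per_scale"`, pinning
`|w| > (1 − rho)·max|w|` within each scale) is available. The headline
setting used throughout the validation is `rho = 0.01`.

## Recurrence quantification

States are delay-embedded (`m` from the first dimension at which Kennel
false-nearest-neighbor fraction reaches ≤1%, ratio threshold 10, absolute
threshold 2 SD; `tau` from the first lag at which the ACF falls inside its
1.96/√N sampling band around zero; fallbacks: curve argmin / first local
minimum). Surrogates always reuse the original's `(m, tau)`.

The recurrence criterion is FAN (fixed amount of nearest neighbors): for
each column `j`, exactly `k = max(1, round(eps·N'))` nearest states (self
included, ties to the lower index) are recurrent, with `eps = 0.07`. Every
column sums to `k` and the recurrence rate is `k/N'` exactly, by
construction — which makes the FAN recurrence plot robust to trends but
also makes RR a degenerate discriminative statistic (it is identical for
original and surrogates; published tables that report RR rejections under
FAN imply some additional matrix masking that this package does not apply).
The Theiler window (= `tau`) excludes the band `|i−j| ≤ tau` from the
diagonal line histogram only; vertical structures and the column-wise
recurrence times include the line of identity.

The 13 indices are RR, DET, ADL, LLDL, ENT (diagonal lines, minimum length
2), LAM, TT, LLVL (vertical lines, minimum length 2), T1 (mean gap between
successive recurrence points within columns), T2 (mean gap between vertical-
structure onsets within columns), RPDE (entropy of the T2 recurrence-time
distribution normalized by ln of the largest observed time), and CC/TRANS
(mean local clustering coefficient and global transitivity of the
OR-symmetrized adjacency with the self-loops removed; nodes of degree < 2
are excluded from the CC average). Indices with empty support return
documented sentinels (0 for line measures, NaN for recurrence times) and
are excluded from testing and aggregation. The whole profile is checked
against an independent loop-based enumeration to 1e-12.

## Restricted weak stationarity

A series is restricted-weakly stationary when mean and variance are stable
across M = 8 segments of L = 50 samples drawn from the N − L + 1 admissible
windows. Normality is assessed with the Lilliefors-corrected KS test (plain
KS with estimated parameters is anti-conservative); non-normal all-positive
series are log-transformed and retested. Normal-branch series use one-way
ANOVA (mean) and Bartlett (variance); otherwise Kruskal–Wallis and Levene
(centered on the mean, the textbook form). The verdict is stationary iff
both p ≥ 0.05.

Two calibration choices matter, because all four tests assume exchangeable
samples and beat-interval or AR data are serially dependent:

* segment starts are drawn *stratified* (one uniform draw per equal bin of
  the admissible positions), which guarantees the segments cover the full
  extent of the series — the purpose random selection serves here;
* each statistic is divided by a variance-inflation factor computed from
  the series' short-lag ACF (lags up to the first zero crossing, capped at
  3): `VIF_mean = 1 + 2Σ(1−k/L)ρ_k` for the mean tests and the analogous
  sum with `ρ_k²` for the variance tests. Fast correlation is thereby part
  of the null; slow structure — wandering mean or variance on the segment
  scale — remains the signal. Without the correction, a perfectly stable
  but correlated series (the broadband AR2 below) is flagged nonstationary
  in about two-thirds of realizations at the nominal 5% level.

Measured operating characteristics (100 seeds, N = 300): broadband AR2
stationary 94%, peaked AR2 nonstationary 78%, i.i.d. noise false alarm
6–7%, random walk nonstationary 100%. The peaked AR2 is in truth a
stationary process whose short realizations merely look unstable, so its
detection fraction trades off directly against the false-alarm rate; 78% is
where an honestly calibrated version of this procedure lands at these
segment sizes.

## Synthetic controls

* `gen_ar2s` — x_t = 0.8 x_{t−1} − 0.25 x_{t−2} + ε, broadband, pole
  modulus 0.5. `gen_ar2ns` — x_t = 1.59 x_{t−1} − 0.96 x_{t−2} + ε, pole
  modulus 0.98, period ≈ 10 samples: a narrowband oscillation whose slow
  amplitude modulation makes 300-sample realizations look nonstationary.
  Both use unit-variance Gaussian innovations (the scale cancels in every
  scale-free statistic downstream), zero initial conditions, 1800 samples
  with the first 1500 discarded.
* `gen_hrv_like` — mean interval + LF sinusoid (0.04–0.15 Hz) + HF sinusoid
  (0.15–0.4 Hz) + white noise, variance split equally so the sample SD
  lands near the target SDNN; an optional random-walk trend of amplitude
  `trend_amp` induces nonstationarity. Defaults (mean 0.8 s, SDNN 0.04 s)
  sit in the middle of the short-term ranges typical of resting adults.
  What it does *not* emulate: respiratory sinus arrhythmia coupling,
  ectopy, quantization, or any genuine nonlinearity — so passing tests on
  it say nothing about nonlinear detection in real recordings.
* `gen_nonlinear_control` — the Hénon map observable with additive noise:
  the true-positive control. PWIAAFT/DET rejects it in 15/15 seeds at
  N = 300, establishing that the test has power against real nonlinearity.

## Validation results the package reproduces, and one it cannot

With LAM as the statistic, fixed (m = 5, tau = 3), 99 surrogates:

* PWIAAFT (rho = 0.01) accepts the linear null on both AR2 processes
  (acceptance 85%/90% over 20 seeds; rejection fraction 10% on both —
  nominal-level behavior).
* IAAFT on the peaked AR2 falsely rejects strongly for the diagonal-mass
  indices (DET at the floor p = 0.01 in 9/10 seeds; ADL/ENT close behind):
  the classical signature of testing a nonstationary-looking series against
  a stationarized null. This residual survives wavelet pinning: PWIAAFT at
  rho = 0.01 still rejects AR2ns with DET in most seeds, and scanning the
  pinned-energy fraction up to 0.8 does not remove it — the joint
  exact-distribution + exact-spectrum constraint itself depresses DET
  relative to a bursty original. Interpretation of diagonal-mass indices on
  strongly nonstationary series should therefore remain guarded even under
  the pinned null; LAM and the other vertical/network indices are the
  calibrated discriminators in that regime.
* IAAFT on the *broadband* AR2 is approximately calibrated (p roughly
  uniform) for every index examined. A floor-p false rejection for LAM on
  both processes is sometimes reported for this setup; that outcome cannot
  be produced by a converged IAAFT implementation on a process that
  satisfies the null exactly — it was checked against end-on-spectrum
  iteration, fixed low iteration counts, alternative Theiler-window
  placements, matrix symmetrization and transposed line counting, none of
  which reproduce it. Under FAN's fixed column density, LAM in particular
  is a weak discriminator, which is also why the peaked-AR2 false rejection
  appears in DET but not LAM here.

## Spectral HRV indices

The tachogram (interval value against cumulative beat time) is linearly
resampled at 3 Hz, mean-removed, and its PSD estimated by Welch averaging
of Hamming-windowed 300-sample segments with 50% overlap ("non-overlapped
window with 50% overlap" is contradictory; 50% overlap is the operative
number). LF integrates 0.04–0.15 Hz, HF 0.15–0.4 Hz; LF/HF is +inf with a
warning when HF is exactly zero. Records must span ≥ 150 s. Ectopic
intervals are flagged by robust z-score (median/1.4826·MAD, falling back to
the mean absolute deviation and then the SD when the MAD degenerates;
threshold 4) and linearly interpolated across unflagged neighbors.

## Aggregation statistics

Rejection percentages carry 95% Jeffreys intervals (Beta(k+½, n−k+½)
quantiles), which reproduce printed rejection-rate intervals of this
literature to the decimal; Clopper–Pearson and Wilson are options.
Proportions are compared by two-sided Fisher exact tests with Bonferroni
correction; distributions by the exact Mann–Whitney U (group sizes ≤ 25
without ties, asymptotic otherwise) with distribution-free order-statistic
CIs for medians; correlations by Spearman's rho.

## Problem sizes and determinism

The validation ensembles use 10–20 realizations per process with 99
surrogates each, and 100 seeds for the stationarity operating
characteristics; these sizes put every Monte-Carlo fraction's standard
error near 3–10 points and complete on a single CPU in a few minutes.
Every random stage takes an explicit seed (per-surrogate seeds are spawned
from the set seed), so all results in this note and the README are exactly
reproducible.

## Known limitations

* The restricted-weak-stationarity test's VIF correction absorbs only
  short-lag correlation; processes with intermediate correlation times
  (10–30 samples) fall between "null" and "signal" and their verdicts drift
  with the cap choice.
* FAN + LAM has little power against nonstationarity by design (fixed
  column density); users testing for nonstationarity-driven effects should
  read DET/ADL/ENT.
* RR is constant under FAN and is reported but never rejects.
* The MODWT smooth is circularly phase-delayed; pinning positions are
  self-consistent across transforms, but coefficient positions should not
  be interpreted as zero-phase time alignment.
* The HRV-like generator is a stand-in for undeposited cohort recordings;
  cohort-level tables computed from it characterize the pipeline, not any
  patient population.
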