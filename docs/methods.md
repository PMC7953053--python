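# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `bhcvr`. Nothing here reports an empirical number that
the test suite or the analysis scripts do not themselves compute.

## Acquisition theory

The `theory` module treats both protocols as spoiled gradient-echo EPI in
steady state. The signal is

S = sin(FA) · (1 − E1) / (1 − cos(FA) · E1),  E1 = exp(−TR/T1),

with T1 = 1.3 s for gray matter at 3 T as the default. BOLD
contrast-to-noise for one echo is CNR(TE) = (S0/σ0) · TE · e^(−TE/T2*),
maximal at TE = T2*; for a weighted echo combination it is
CNR = Σ W_n TE_n S_n / (σ √ΣW_n²) with S_n = e^(−TE_n/T2*) and weights
W_n ∝ TE_n e^(−TE_n/T2*) normalized to sum to one. The summation index in
the denominator runs over all echoes n = 1..N.

Two conventions are deliberate:

- The multi-/single-echo **CNR ratio includes the steady-state factor** of
  each protocol, because the two protocols run at different TRs and
  therefore different S0. At the reference parameters the ratio factors as
  (echo-combination gain ≈ 1.59) × (steady-state gain ≈ 1.18) ≈ 1.88.
- S0/σ0 defaults to 1 and σ is assumed equal across echoes and protocols;
  only ratios are meaningful at this level of modeling. Noise covariance
  across coils, ramp-sampling effects and field-strength dependence of T2*
  are out of scope.

Angles are degrees at the interface, radians internally.

## Task model

The breath-hold paradigm is a block design totalling 320 s: 66 s paced
breathing, four cycles of 24 s paced / 16 s hold / 16 s recovery
(56-s cycle, task fundamental 1/56 Hz), then 30 s paced. Paced breathing is
3 s in / 3 s out, i.e. a 1/6 Hz ≈ 0.17 Hz respiratory oscillation.

The expected response is the hold-period boxcar convolved with the
respiration response function

RRF(t) = 0.6 t^2.1 e^(−t/1.6) − 0.0023 t^3.54 e^(−t/4.25),

which peaks near 3.1 s and has a long negative undershoot (minimum near
15 s). Numerically the convolution runs at dt = 0.1 s with the kernel
truncated at 60 s; the kernel tail at 60 s is ≈ 3.4e−3, about 0.4% of the
kernel peak, a negligible truncation for regressor construction.

Because regional hemodynamic delay varies by several seconds, the
regressor is replicated at lags −8 … 16 s in 2-s steps (13 columns).
Lag-shifting happens on the fine grid (integer dt samples) before sampling
at volume-acquisition times t_i = (n_discarded + i)·TR; frame-onset times
are used and slice timing is ignored. **One normalization scale** — the
positive peak of the lag-0 sampled column — is applied to all columns, so
a fitted β is the peak response amplitude in signal units and is
comparable across lags. Peak means the positive task peak: the convolved
undershoot lobe is larger in absolute value (the RRF's negative integral
dominates its positive one), and normalizing by it would flip the sign
convention of β.

## Synthetic data

The generator exists so that every pipeline stage can be validated by
parameter recovery. It emulates:

- a head as an ellipsoid with a gray-matter shell (T2* 50 ms, S0 1000), a
  white-matter core (T2* 45 ms), and a small low-T2* pocket (20 ms)
  standing in for orbitofrontal susceptibility dropout;
- four gray-matter quadrant ROIs with piecewise-constant task amplitude
  ΔR2* ∈ {0.3, 0.5, 0.7, 0.9} s⁻¹ and lag ∈ {−4, 0, 6, 10} s. The
  amplitudes correspond to peak percent signal changes of about 1–3% at
  the default echo times, the range typically reported for breath holds at
  3 T; the lags sit on the analysis grid so "exact recovery" is well
  defined;
- the BOLD effect as an R2* *decrease* — S(v,t,e) = S0 e^(−TE_e·R2*(v,t)/1000)
  — so the TE dependence of the percent signal change emerges from the
  physics rather than being imposed;
- multiplicative nuisance: a 1/6 Hz respiratory oscillation (fractional
  amplitude 0.003) and a cubic drift (fractional Legendre coefficients
  (0.005, −0.002, 0.001)); and additive white Gaussian thermal noise,
  independent per echo, default σ = 3 signal units. That default places
  normalized gray-matter tSNR (tSNR·√N_TP) of the combined series in the
  low thousands, the order of magnitude seen in vivo; no quantitative
  noise level is prescribed by the physiology, so this is an explicit
  modeling choice.

Test–retest pairs draw an independent multiplicative lognormal
perturbation of the amplitude map *per session* (mean 1, configurable CV)
plus independent noise. Independent-per-session jitter is what makes the
pair's amplitude wCV scale as |N(0, CV)| (median 0.6745·CV); perturbing
only one session would understate it by √2. Zero jitter and zero noise
reproduce a session bitwise.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: subject motion and its interaction with
distortion, cardiac pulsatility, B0 inhomogeneity beyond a static short-T2*
pocket, spatially varying hemodynamic response shapes, breath-hold
compliance failures, and physiological noise that scales with signal.

## Echo combination

T2* is fit per voxel by log-linear least squares of the time-mean signal
against TE (static weighting; time-resolved T2* is out of scope). Voxels
with a nonpositive mean at any echo or a non-decaying slope are marked
invalid and clamped to the ceiling of the [5, 300] ms clamp, which keeps
weights finite in background and dropout regions; 5–300 ms spans the
physiologic range at 3 T. Combination uses the CNR-optimal weights
W_n ∝ TE_n e^(−TE_n/T2*) held constant over time. For equal per-echo noise
σ the combined noise SD is σ√ΣW², a ≈ 40% reduction for the reference
echo times at T2* = 50 ms.

## Preprocessing

- **Discard**: the first 10 volumes are dropped; the discard count shifts
  the regressor sampling times.
- **Detrending / drift**: a standalone third-order Legendre polynomial
  detrend (mean-preserving, idempotent) is provided, but the default
  pipeline fits drift *jointly* with the task regressor by passing the
  polynomial columns as GLM nuisance regressors. The BH regressor's
  undershoot carries genuine low-frequency energy; detrending first
  projects part of the task response out of the data and biases β low by
  several percent, while the joint fit is unbiased. The cubic basis also
  absorbs ~2.5% of a pure 1/56 Hz sinusoid's amplitude over a 320-s run —
  inherent overlap, not an implementation artifact.
- **Smoothing**: separable Gaussian, σ = FWHM/(2√(2 ln 2)) (1.70 mm for
  4 mm FWHM), zero-padded boundaries. The pipeline default is FWHM 0 on
  the phantom (its ROIs are piecewise-constant; smoothing would only blur
  compartment edges), with 4 mm available for real-data workflows.
- **Task notch**: component-based denoising can misclassify the
  high-variance BH response as noise, so components are estimated on a
  copy of the data with the task frequency suppressed and then regressed
  out of the *original* series; `regress_confounds` enforces that ordering
  when a table is tagged `estimated_on_filtered`. The notch itself removes
  an exact least-squares sin/cos pair at f0 (demeaned, so DC is untouched)
  and zeroes the remaining DFT bins within ±0.005 Hz of f0. The explicit
  projection matters because 1/56 Hz is not a DFT bin frequency of a
  313-s record: plain bin-zeroing leaves ~35% of an off-bin sinusoid as
  spectral leakage, whereas the hybrid attenuates it to machine precision
  while changing a 0.1 Hz sinusoid's amplitude by < 0.1%. Harmonic removal
  is available behind a flag; the default suppresses only the fundamental,
  with the bandwidth an explicit choice. Note that detrend and notch do
  not commute (polynomial drift has substantial energy inside the stop
  band), so the pipeline fixes the order: drift handling first, notch
  second.
- **tSNR**: mean/SD over time with sample SD (n−1, consistently with the
  wCV convention), normalized by √N_TP to compare runs of different
  length; zero-SD voxels are flagged rather than infinite.

## The breath-hold GLM

Per voxel and per lag, ordinary least squares of the series on
[intercept, drift columns, lagged regressor]; the lag with the highest
positive t on the task column is selected, ties breaking toward the
smaller lag for determinism. Degrees of freedom are charged once for the
selected task column (the design fits one regressor at a time, mirroring
deconvolution practice) plus all nuisance columns and any previously
regressed confounds. Selecting the maximum t over 13 correlated lags
inflates the null distribution — the suite measures a ~4% empirical rate
at a nominal 1% threshold on white noise — and no multiplicity correction
is applied, reproducing the analysis convention this pipeline models;
interpret voxelwise p-values accordingly.

t-scores convert to z through the two-sided probability-preserving map
z = Φ⁻¹(F_t(t; ν)) evaluated through log survival functions, which keeps
|t| > 8 from saturating. Activation masks threshold one-sided
(z > Φ⁻¹(1−p), 2.326 at p = 0.01), consistent with the positive-t
selection rule.

CVR is the percent signal change 100·β/mean, with the mean taken from the
pre-detrend series (the detrend is mean-preserving, so the choice is
consistent either way; both pre- and post-smoothing means are accessible).
rCVR divides by the mean CVR over the gray-matter mask, exactly
normalizing the gray-matter mean of rCVR to 1 and cancelling the
effective-TE dependence of the percent signal change.

Temporal autocorrelation: an optional voxelwise Cochrane–Orcutt AR(1)
prewhitening (ρ from the lag-1 autocorrelation of OLS residuals,
quasi-differenced refit, one degree of freedom charged) is provided,
default off. It is an approximation to full ARMA(1,1) restricted-maximum-
likelihood prewhitening, which is out of scope; with white synthetic noise
the OLS and AR(1) paths agree closely.

## Reliability metrics

Dice uses p < 0.01 one-sided activation masks; the both-empty case is
flagged undefined rather than 0 or 1. wCV for a session pair is the
sample SD (|a−b|/√2) over the pair mean, flagged where the mean is
nonpositive; summaries average over valid gray-matter voxels. ICC(3,1) is
the two-way mixed, consistency, single-measurement form
(BMS − EMS)/(BMS + (k−1)·EMS) from the subjects × sessions ANOVA,
computed on rCVR by default (CVR optional), with listwise deletion of
subjects missing a session; it is cross-checked in the tests against an
independent ANOVA implementation to 1e−9. ICC summaries report the
percentage of gray-matter voxels above 0.4 / 0.6 / 0.8, over gray matter
only. ROI comparisons use paired t-tests with Bonferroni correction
(multiply by the number of tested ROIs, cap at 1); zero-variance
difference vectors are flagged degenerate, and ROIs with fewer than two
paired subjects are excluded.

## Problem sizes and validation regimes

The default phantom is 24 × 24 × 12 voxels of 3 mm — a desk-scale volume
matching the voxel size of the modeled acquisition — and the cohort
analyses (reliability, ICC-vs-noise) use 16 × 16 × 8 phantoms with 20
subjects, sizes at which the full multi-subject pipeline runs in seconds
while leaving every compartment resolvable.

Amplitude-recovery checks run in two regimes on purpose. The *default*
conditions (ΔR2* up to 0.9 s⁻¹, thermal noise on) exercise detection, lag
recovery and reliability at realistic effect sizes. The *linear-regime*
round trip (amplitudes scaled by 0.1, zero noise) is where recovered β is
compared against the generator's closed form at the 1% level: a linear
regressor fit to the exponential signal model carries an intrinsic
linearization bias of roughly 1.9 × (ΔR2*·TE_eff/1000) — a few percent at
full amplitude, driven mostly by the regressor's deep undershoot — so
implementation correctness is only identifiable against the closed form
where that method bias is negligible. The bias is a property of the
percent-signal-change method itself, not of this implementation.

## Known limitations

- No motion correction, registration, distortion correction or slice
  timing: inputs are assumed aligned; those stages belong to upstream
  tooling.
- ICA-based denoising is represented only by its interface (a confound
  table plus the notch-prefilter ordering contract), not by a
  decomposition algorithm.
- The AR(1) option approximates, and the default OLS path ignores,
  temporal autocorrelation; synthetic thermal noise is white, so the
  tests do not probe misspecified autocorrelation.
- Group-level mixed-effects modeling and cluster-extent inference are out
  of scope; ROI paired t-tests are the only group operation.
- The phantom's piecewise-constant ROIs make spatial smoothing
  counterproductive in simulation studies; smoothing defaults reflect
  that and must be revisited for real data.
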