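# bhcvr

Breath-hold cerebrovascular reactivity (CVR) mapping from multiband
multi-echo BOLD fMRI, as a tested, self-contained analysis pipeline.

## The problem

Cerebrovascular reactivity — how strongly cerebral vessels dilate in
response to a CO2 challenge — is an emerging marker of neurovascular
health. A practical way to measure it is a breath-hold (BH) task during
BOLD fMRI: end-expiration holds raise arterial CO2 and produce a slow,
regionally delayed BOLD response. Echo-planar imaging at a single echo
time, however, suffers signal dropout where T2* is short (orbitofrontal and
inferior temporal cortex), and its BOLD sensitivity depends on how well TE
matches the local T2*. Acquiring several echoes per excitation and
combining them with T2*-derived weights recovers sensitivity across the
brain, at the cost of a longer TR.

`bhcvr` implements the full analysis this comparison needs, for
researchers who want to study the method itself rather than any one
dataset:

- **theory** — closed-form acquisition calculations: steady-state spoiled
  gradient-echo signal `S = sin(FA)(1 − e^(−TR/T1))/(1 − cos(FA) e^(−TR/T1))`,
  Ernst angle `arccos(e^(−TR/T1))`, echo-combination weights
  `W_n ∝ TE_n e^(−TE_n/T2*)`, and single/multi-echo contrast-to-noise
  `CNR(TE) = (S0/σ0)·TE·e^(−TE/T2*)` and
  `CNR_multi = Σ W_n TE_n S_n / (σ √Σ W_n²)`.
- **task_design** — the 320-s BH paradigm (66 s lead-in, 4 × [24 s paced /
  16 s hold / 16 s recovery], 30 s lead-out), the respiration response
  function `RRF(t) = 0.6 t^2.1 e^(−t/1.6) − 0.0023 t^3.54 e^(−t/4.25)`, and
  the family of regressors lag-shifted over −8…16 s in 2-s steps.
- **synthetic** — a digital head phantom and multi-echo session generator
  with known ground truth (S0, baseline R2*, task ΔR2*, hemodynamic lag),
  so every downstream stage is validated by parameter recovery.
- **echo_combine** — voxelwise log-linear T2* fitting and T2*-weighted
  echo combination.
- **preprocess** — volume discard, polynomial detrending, Gaussian
  smoothing, a task-frequency (1/56 Hz) notch prefilter for
  component-based denoising, confound regression with degrees-of-freedom
  bookkeeping, and tSNR maps (`tSNR·√N_TP` normalization).
- **glm** — the voxelwise BH GLM: per lag, OLS of the combined series on
  the lagged regressor; the lag with the highest positive t wins;
  t → z via the probability-preserving CDF mapping with adjusted degrees
  of freedom; CVR = 100·β/mean signal (percent signal change); relative
  CVR (rCVR) = CVR / mean gray-matter CVR.
- **repeatability** — Dice overlap of thresholded activation masks
  `DC = 2|A∩B|/(|A|+|B|)`, within-subject coefficient of variation,
  voxelwise ICC(3,1) `= (BMS − EMS)/(BMS + EMS)` for two sessions, ICC
  threshold summaries, and Bonferroni-corrected paired t-tests on ROI
  means.

## Worked example

The numbered scripts under `analysis/` tell the story end to end; each
writes its tables under `results/`. For instance:

```text
$ python analysis/01_theory_cnr.py
steady-state signal: multi-echo (TR 0.9 s) 0.5770, single-echo (TR 0.65 s) 0.4891, ratio 1.180
Ernst angles: TR 0.65 s -> 52.7 deg, TR 0.90 s -> 60.0 deg (both protocols use 60 deg)
CNR ratio (3-echo combination vs TE=30 ms) at T2* = 50 ms, steady-state factor included: 1.879
CNR ratio rises monotonically with T2* above 25 ms: True
```

The longer TR of the three-echo protocol buys an 18% steady-state signal
gain, and the T2*-weighted combination multiplies that to a ~1.9× CNR
advantage over the single 30-ms echo at a typical gray-matter T2* of
50 ms.

```text
$ python analysis/03_recover_cvr.py
linear-regime round trip: lag exact in 100% of GM, max amplitude error 0.77%, rCVR GM mean 1.000000000
default conditions: lag within +-2 s in 100.0% of GM, GM mean CVR 1.75%
 roi  true_delta_r2star  true_lag_s  recovered_lag_mode_s  mean_cvr_percent  mean_rcvr
   1                0.3        -4.0                  -4.0          0.886386   0.507933
   2                0.5         0.0                   0.0          1.467563   0.840969
   3                0.7         6.0                   6.0          2.041511   1.169862
   4                0.9        10.0                  10.0          2.608692   1.494878
echo combination beats first echo in 100.0% of GM (median z 33.0 vs 21.8)
```

Every gray-matter voxel recovers its true hemodynamic lag, fitted
amplitudes match the generator's closed form, CVR scales linearly with the
imposed ΔR2* (0.89–2.61% signal change for 0.3–0.9 s⁻¹), and the
T2*-weighted combination raises the BH z-score over the short-TE echo in
all of gray matter.

```text
$ python analysis/04_retest_reliability.py
cohort of 20 subjects, 638 GM voxels
Dice (p<0.01 masks): 1.000 (0.000)
GM wCV: 0.078 (0.003); |rCVR| difference: 0.110
voxelwise ICC(3,1) in GM: mean 0.750; % voxels above 0.4/0.6/0.8: 99.2/90.4/36.7
ROI rCVR, combined vs first echo: 0/4 ROIs differ after Bonferroni correction
```

With a mild day-to-day amplitude jitter (CV 0.1) the simulated cohort
lands in the "good" reliability band (mean ICC 0.75), and — because rCVR
normalizes out the effective-TE dependence of the percent signal change —
ROI-level rCVR is statistically indistinguishable between the combined-echo
and single-echo analyses of the same data.

A `bhcvr` console command exposes the stages individually
(`theory`, `simulate`, `combine`, `preprocess`, `glm`, `retest`) and as a
configured pipeline (`bhcvr run --config cfg.yaml`).

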