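# Methods

This note documents the generative model behind the phantom, the
quantification conventions, the numerical choices, and what the synthetic
validation does and does not demonstrate about real data.

## Tracer-kinetic model

Every labeled region follows reversible compartmental kinetics driven by a
single shared plasma input `Cp(t)`. For a one-tissue region,

    dCt/dt = K1·Cp(t) − k2·Ct(t),        DV = K1/k2,

with `K1` in mL·g⁻¹·min⁻¹ and `k2` in 1/min. The solution is the
convolution `Ct = K1·(Cp ∗ e^{−k2 t})`, evaluated in closed form because
`Cp` is a sum of exponentials (the degenerate case `k2 = λ` uses the limit
`K1·a·t·e^{−k2 t}`). A one-tissue description is appropriate for a highly
lipophilic, rapidly equilibrating substrate-type tracer and is the simplest
model consistent with reference-tissue Logan analysis.

**Why the reference region has a second component.** For two one-tissue
regions sharing an input, the ratio of tissue curves
`(Cp ∗ e^{−a t})/(Cp ∗ e^{−b t})` is monotone in time for *any*
non-negative input (a total-positivity property of exponential kernels), so
a pure one-tissue phantom cannot produce the transient tumor-to-brainstem
contrast that peaks at 15–20 min and declines afterwards — the ratio would
keep rising until the end of the scan. The phantom therefore gives the
brainstem impulse response a small slowly-clearing term:

    h_ref(t) = K1·[(1 − f)·e^{−k2 t} + f·e^{−k2_slow t}],   f = 0.12,
    k2 = 0.6/min, k2_slow = 0.08/min,

interpretable as minor nonspecific retention. Early on, the fast component
clears and the tumor/brainstem ratio rises; late, the slow residual
dominates the brainstem while the tumor washes out, and the ratio falls.
With the default parameters the contrast peaks at the 16.5-min frame. The
region's total DV is the integral of the impulse response,
`DV = K1·[(1−f)/k2 + f/k2_slow]`, and reference-tissue Logan analysis
remains valid (both regions are reversible); the noiseless fit recovers the
true tumor-rim/brainstem DV ratio to within 1%.

## Plasma input

    Cp(t) = Σ aᵢ·e^{−λᵢ (t−d)}  for t ≥ d,  0 before,

with default amplitudes `2.116·(1, 0.25, −1.25)` µCi/mL, rates
`(0.25, 0.035, 3.0)` /min and delay `d = 0.25` min: a bolus that rises over
roughly a minute, washes out fast, and keeps a slow tail. The study never
sampled blood; this shape is a modeling choice with the properties the
analysis needs (brainstem TAC peaking inside the first 5 min, tissue curves
of realistic magnitude) and is not claimed as physiological truth.
Construction validates non-negativity of the curve on [0, 90] min.

## Geometry, frames, noise

* Grid: 64³ voxels of 0.5 mm; regions are spheres/shells in 0-based voxel
  coordinates, pairwise disjoint by construction (overlap is an error).
  The tumor is a shell (viable rim, 410 voxels) around a low-uptake core
  (necrotic, 515 voxels); brainstem, cortex, hippocampus, nucleus
  accumbens and cerebellum are spheres.
* Frames: 60 × 1-min contiguous frames over 0–60 min. Frame values are the
  analytic TAC averaged over the frame interval using 21 trapezoid points
  per frame (midpoint evaluation is biased for 1–2 min frames on fast
  kinetics).
* Noise: zero-mean Gaussian per voxel with standard deviation
  `noise_level·sqrt(Ct/Δt)`, seeded and bit-reproducible. The default
  `noise_level = 0.05` corresponds to ≈5% voxel noise at the tumor-rim
  activity level on 1-min frames, emulating post-smoothing
  reconstructed-image noise. Projection-domain (Poisson) noise,
  reconstruction artifacts, attenuation, scatter and partial-volume effects
  are all outside the model.
* Physical ¹⁸F decay (half-life 109.77 min) can be applied optionally; by
  default the phantom stores decay-corrected concentrations, as scanners
  output.

## Calibration

The default kinetic table is *calibrated, not measured*: plasma scale and
region parameters were fixed once so that the noiseless pipeline reproduces
the study-level summary values used as simulation ground truth —

| readout (20-min frame) | calibrated value |
|---|---|
| tumor upper-quartile SUV | 1.110 |
| tumor/brainstem SUV ratio | 2.730 |
| peak tumor/brainstem contrast | 16.5 min (within 15–20) |
| EX-527 tumor-DV fraction | 0.60 (≈40% inhibition) |

Regional DVs (mL/g): tumor rim 2.08, tumor core 0.63, brainstem 0.92,
cortex 0.95, cerebellum 1.00, hippocampus 1.25, nucleus accumbens 1.30 —
encoding the assumed biology (rim highest; hippocampus/nucleus accumbens
elevated; brainstem low, hence its use as reference; necrotic core lowest).
The source literature reports both "almost 2-fold" and "about 40%"
inhibition for the same EX-527 effect; the default effect fraction follows
the 40% figure, and the discrepancy is noted here rather than resolved.

## Cohorts and treatment

`make_cohort` draws injected dose from 300–500 µCi and body weight from
400–500 g per subject and scales the plasma amplitudes by dose/weight, so
SUV is comparable across subjects (as it is designed to be). Between-subject
kinetic variability multiplies each region's K1 by a normal factor with
CV = 0.05 (k2 held), so true DV inherits exactly that CV. Noise seeds
derive deterministically from the master seed.

`apply_treatment` scales tumor-region DV by the drug's tumor fraction
(implemented on K1, leaving delivery-phase washout untouched) and
off-target DV by the off-target fraction. Defaults: EX-527 = (0.6, 1.0),
MC1568 = (1.0, 1.0). Drug arms are paired: each subject keeps its jittered
kinetics between baseline and post scans and only the treatment scaling and
the noise realization differ, mirroring a within-animal design.

## Quantification conventions

* Units: µCi and µCi/g internally; 1 µCi = 37 kBq is available as a
  constant, never applied implicitly.
* TAC: per-frame arithmetic mean over region voxels; a union of regions
  (rim + core = "tumor") is averaged with voxel-count weights.
* "20 min post-injection" means the frame whose midpoint is closest to
  20 min, earlier frame on ties (the 19.5-min frame on the default grid).
* Upper-quartile tumor SUV: 75th percentile under linear interpolation
  (rank 0.75·(n−1)); voxels tied with the threshold are included. The
  convention is a documented choice — the statistic's originators did not
  state one. Applied to tumor ROIs only; normal regions use plain means.
  Under noise the statistic is biased upward by construction (it selects
  the upper tail): with default noise the cohort-mean tumor SUV runs ~2–4%
  above the noiseless value, well inside the acceptance band.

## Logan analysis

* Cumulative integrals are trapezoidal with an implicit (0, 0) sample at
  injection. For a decaying-only curve (nonzero at t = 0) this start
  convention leaves a persistent early deficit; tissue curves are
  bolus-shaped (zero at injection), for which late-phase integrals agree
  with closed forms to <1% on the default grid.
* The `C_ref(T)/k2′` term is omitted by default: with the fast-clearing
  reference its inclusion changes the DVR by <2%, and no k2′ value is
  available in practice without an additional fit. An explicit `k2prime`
  may be supplied.
* The slope is reported as `dvr` (with a `dv_paper` alias in JSON output):
  without arterial input the reference-tissue Logan slope is a
  distribution-volume *ratio*, even where summary tables call it "DV".
* t\* policy: fixed t\* = 20 min by default in the pipeline (the readout
  time); `select_t_star` alternatively chooses the earliest start whose
  late-phase fit has maximum relative residual ≤ 0.10, falling back to the
  latest third of the scan with a warning. Fits use unweighted OLS and
  require ≥ 3 points; R² is computed on the fitted points only.

## Statistics

* One-way ANOVA (regions at baseline): classical F = MSB/MSW with
  df (k−1, N−k).
* Treatment effects: two-condition repeated-measures F, computed as the
  squared paired t statistic with df (1, n−1); two-sided; the effect is the
  percent change of condition means. Multi-condition designs are out of
  scope. No multiplicity correction by default (a Holm adjustment is
  provided for multi-region tables).
* Summaries report mean ± SEM (SD/√n); SEM is NaN for n = 1.

## Problem sizes

The shipped validation uses the full default grid (64³ × 60 frames): six
baseline subjects for the summary-value recovery, three paired subjects per
drug arm, noiseless single subjects for recovery/identity checks, 200
spec-level subjects for the jitter Monte-Carlo, and 400 summary-level
cohorts for the type-I-error calibration of the paired test. These sizes
give comfortable statistical resolution for every tolerance tested (e.g.
binomial SE ≈ 1.1% on the 5% rejection rate) while keeping the whole suite
around half a minute.

## What passing tests do and do not show

The phantom shares the analysis pipeline's own forward conventions
(frame-averaged means, shared grid, perfect segmentation), so end-to-end
recovery demonstrates internal correctness of the quantification — not
robustness to segmentation error, motion, partial-volume effects,
reconstruction bias, or deviations of real tracer kinetics from the
one-tissue model. The calibrated defaults make the pipeline reproduce
summary values *by construction*; the informative checks are that
estimation is unbiased against ground truth under noise and jitter, that
the paired test is calibrated under the null, and that every computational
primitive matches an independent oracle.

## Known limitations

* Gaussian image-domain noise only; no Poisson/sinogram simulation.
* No arterial-input Logan, SRTM, or voxelwise parametric images.
* Geometry limited to spheres and shells on one grid; no co-registration.
* Two-condition repeated-measures only; no mixed models or sphericity
  machinery.
* The MC1568 (null) arm's non-significance is a single draw per seed: under
  the null the p-value is uniform, so ~5% of seeds will produce a spurious
  rejection — that is the correct behavior of a calibrated test, not a
  defect.
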