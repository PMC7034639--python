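# petquant

Quantitative analysis of dynamic small-animal PET for imaging SIRT1
expression–activity in intracerebral 9L glioma, together with a calibrated
4D digital rat-brain phantom that makes the whole pipeline testable without
any acquired data.

`petquant` is written for imaging scientists who quantify substrate-type
radiotracer uptake in rodent brain-tumor models: it extracts region
time–activity curves (TACs) from 4D NIfTI volumes, computes standard uptake
values — including the upper-quartile tumor statistic used for
heterogeneous gliomas — forms tumor-to-brainstem SUV ratios, estimates
distribution-volume ratios by reference-tissue Logan graphical analysis,
and runs the paired statistics needed to read out pharmacologic target
engagement (SIRT1 inhibition by EX-527, with the class-IIa HDAC inhibitor
MC1568 as specificity control).

## The quantities it computes

**SUV.** Tissue concentration normalized by injected dose per gram of body
weight:

    SUV(t) = C_tissue(t) [µCi/g] / (D [µCi] / W [g])

For tumors the reported statistic is the *upper-quartile mean*: the mean
SUV of tumor-ROI voxels at or above the 75th percentile (linear
interpolation convention), isolating the high-uptake viable rim from the
necrotic core.

**Reference-tissue Logan DVR.** For reversible kinetics the plot of
`∫₀ᵀ C_t dt / C_t(T)` against `∫₀ᵀ C_ref dt / C_t(T)` becomes linear after
an equilibration time t\*, with slope equal to the distribution-volume
ratio (DVR) between target and reference. The brainstem serves as the
reference (low SIRT1, perfusion comparable to the rest of the brain). The
`C_ref(T)/k2′` term of the full formulation is omitted by default and
available as an option.

**Phantom.** Each region follows one-tissue compartment kinetics
`dCt/dt = K1·Cp − k2·Ct` (DV = K1/k2) driven by a shared sum-of-exponentials
plasma bolus; the brainstem additionally carries a small slow nonspecific
washout component, which is what makes the tumor-to-brainstem contrast
transient with a peak in the 15–20 min window (see `docs/methods.md`). The
default kinetic table is calibrated so the noiseless pipeline reproduces
the study-level summary values used as simulation ground truth: tumor
upper-quartile SUV 1.11 at 20 min, tumor/brainstem ratio 2.73, and a 40%
tumor-DV reduction under EX-527.

## Worked example

```python
from petquant import (build_phantom, default_phantom_spec, extract_tac,
                      logan_dvr, compute_suv, tumor_suv_upper_quartile)
from petquant.quantify import voxel_suvs_at_frame

spec = default_phantom_spec(seed=42, noise_level=0.05)
image, labels, meta, truth = build_phantom(spec)

f20 = image.frames.closest_frame(20.0)
vox = voxel_suvs_at_frame(image, labels, ["tumor_rim", "tumor_core"], f20, meta)
tumor_suv = tumor_suv_upper_quartile(vox)
bs_tac = extract_tac(image, labels, "brainstem")
bs_suv = float(compute_suv(bs_tac.values[f20], meta))
tumor_tac = extract_tac(image, labels, ["tumor_rim", "tumor_core"])
fit = logan_dvr(tumor_tac, bs_tac, t_star=20.0)

print(f"tumor upper-quartile SUV @ {image.frames.midpoints[f20]:.1f} min: {tumor_suv:.3f}")
print(f"tumor/brainstem SUV ratio: {tumor_suv / bs_suv:.3f}")
print(f"tumor Logan DVR (t*=20 min): {fit.dvr_slope:.3f}  (R^2={fit.r_squared:.4f})")
print(f"ground-truth tumor-rim DV / brainstem DV: {truth['tumor_rim']/truth['brainstem']:.3f}")
```

prints

```
tumor upper-quartile SUV @ 19.5 min: 1.152
tumor/brainstem SUV ratio: 2.841
tumor Logan DVR (t*=20 min): 1.394  (R^2=1.0000)
ground-truth tumor-rim DV / brainstem DV: 2.263
```

The SUV of 1.152 and ratio of 2.841 sit a few percent above the noiseless
calibration values (1.11 and 2.73) because the upper-quartile statistic
selects the upper tail of the voxel-noise distribution; the fitted DVR of
1.394 is the voxel-weighted rim+core value (the rim alone fits to ≈ 2.28
against its ground truth of 2.263).

The same stages are available from the shell:

```sh
petquant simulate --out sim/ --seed 3 --n 1
petquant quantify --image sim/S01.nii.gz --frames sim/S01_frames.csv \
    --labels sim/S01_labels.nii.gz --names sim/S01_labels.csv \
    --meta sim/S01_meta.yaml --out quant/
petquant logan --tacs quant/tacs.csv --target tumor_rim --reference brainstem \
    --t-star 20 --out logan.json
petquant run-all --out runs/demo --seed 1     # full 3-arm experiment + report
```

## Layout

- `petquant.phantom` — kinetic forward model, geometry, cohort simulation
- `petquant.io` — NIfTI/CSV/YAML/JSON readers and writers with validation
- `petquant.quantify` — TACs, decay correction, SUV, upper-quartile, ratios
- `petquant.kinetics` — Logan transform, t\* selection, DVR fitting
- `petquant.stats` — one-way ANOVA, paired repeated-measures test, summaries
- `petquant.pipeline` / `petquant.cli` — config-driven orchestration

See `docs/methods.md` for the model assumptions, calibration, numerical
conventions and known limitations.
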