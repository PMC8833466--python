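# pancdwi

Computed high b-value diffusion-weighted MRI (cDWI) for pancreatic-tumor
conspicuity, as a fully synthetic, testable analysis pipeline.

## The problem

Pancreatic ductal adenocarcinoma (PDAC) restricts water diffusion less than
it might seem on standard DWI: at moderate diffusion weighting
(b ≤ 600 s/mm²) the surrounding parenchyma retains signal (T2 shine-through,
perfusion), obscuring the tumor. High b-value images (b = 1000 s/mm²)
suppress the parenchyma and make the lesion conspicuous — but acquiring them
costs scan time and signal-to-noise. **Computed DWI** sidesteps the
acquisition: fit the mono-exponential decay

    S(b) = S0 · exp(−b · ADC)

voxel-wise over the acquired b-values (here 0/50/300/600 s/mm²) by
log-linear least squares, then synthesize the image at any target b:

    S_c(b*) = S0 · exp(−b* · ADC)

This package implements that chain for an in-silico reader study comparing
five datasets per patient — acquired b600 and computed b1000 in a
conventional full-FOV geometry (3×3×4 mm voxels) and a high-resolution
reduced-FOV geometry (2.5×2.5×3 mm), plus the directly acquired rFOV b1000:

- **phantom / cohort** — digital abdomens (curved pancreas band, embedded
  lesion, duct, background) with tissue-wise diffusion parameters, optional
  perfusion (IVIM) contamination, acquisition PSF blur, and per-excitation
  Rician magnitude noise averaged as the scanner averages NSA;
- **cdwi** — voxel-wise mono-exponential fitting (OLS / WLS / nonlinear LS)
  and computed-DWI synthesis at arbitrary b;
- **roi** — 5-mm disc ROIs in tumor and proximal/distal parenchyma,
  cross-grid propagation, and the apparent contrast metrics
  `aSNR = SI_p/SD_p`, `aCNR = (SI_t − SI_p)/SD_p`, `CR = SI_t/SI_p`;
- **readers** — a three-reader 4-point Likert panel (image quality, lesion
  detection, DWI signal-intensity type) via a cumulative-threshold ordinal
  model calibrated to almost-perfect agreement;
- **stats** — Wilcoxon signed-rank (exact sign-flip null or tie-corrected
  asymptotic), Friedman with tie correction, Dunn–Bonferroni post hoc,
  Fleiss' κ with agreement bands, Lilliefors/KS normality;
- **study** — the full orchestration (cohort → cDWI → metrics → readers →
  statistics) plus cohort-exclusion and scan-time bookkeeping.

## A worked example

```sh
python examples/04_full_study.py
```

runs a 46-patient study on reduced 64×64×8 grids and prints, among other
tables:

```
=== quantitative metrics (mean +/- SD) ===
                     asnr           acnr  cr_proximal    cr_distal
dataset_id
f-aDWI600   30.82 ± 38.12  11.79 ± 12.66   1.4 ± 0.16  1.41 ± 0.22
f-cDWI1000   14.91 ± 12.2   11.9 ± 14.35  1.77 ± 0.36  1.81 ± 0.46
r-aDWI600    16.51 ± 9.32    9.88 ± 5.19  1.63 ± 0.18  1.62 ± 0.17
r-cDWI1000    9.95 ± 4.37    12.1 ± 5.86  2.26 ± 0.41  2.24 ± 0.41
r-aDWI1000     9.0 ± 3.05    6.23 ± 2.94  1.67 ± 0.28  1.73 ± 0.25

scan-time saving of computing instead of acquiring b=1000: 78%
```

Reading the numbers: computed b=1000 datasets trade apparent SNR (9.95 vs
16.51 in the rFOV geometry) for lesion contrast — CR rises from 1.63 to 2.26
and aCNR from 9.88 to 12.1 — and the high-resolution computed dataset beats
both the conventional computed and the acquired high-b datasets on
aCNR/CR. The b=1000 information comes from a 3:18-min acquisition instead
of 15:00 min, a 78% scan-time reduction.

The other examples are single-capability walkthroughs: `01` phantom +
computed-DWI exactness, `02` ROI metrics and the closed-form contrast ratio
CR(b) = exp((ADC_p − ADC_l)·b), `03` the statistical battery on simulated
ratings.

A thin CLI mirrors the stages:

```sh
pancdwi generate --n 46 --seed 7 --grid 64,64,8 --out cohort/
pancdwi compute --in cohort/P001_rFOV.nii.gz --bvals 0,50,300,600 --btarget 1000 --out maps/
pancdwi measure --volume cohort/P001_rFOV.nii.gz --b 600 --rois rois.json --out metrics.csv
pancdwi run-study --n 46 --seed 7 --grid 64,64,8 --out report/
```

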