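# Methods

This note documents the models behind `pancdwi`: what is simulated, which
parameters matter, the numerical conventions, and the limits of what the
synthetic experiments can show.

## Signal model

Every tissue carries a signal at b=0 (`s0`, arbitrary units) and an apparent
diffusion coefficient (`adc`, mm²/s, clamped to [0, 4e-3]); the noiseless
diffusion-weighted signal is mono-exponential, S(b) = S0·exp(−b·ADC).
Tissues may additionally define a perfusion (IVIM) component with fraction
`f` and pseudo-diffusion `D*`:

    S(b) = S0 · [(1−f)·exp(−b·ADC) + f·exp(−b·(ADC + D*))]

The bare phantom default is `f = 0` (pure mono-exponential), which keeps the
closed-form identities exact: fitting noiseless data recovers S0/ADC to
round-off, extrapolation to any b is exact, and the lesion/parenchyma
contrast ratio is exp((ADC_p − ADC_l)·b) when S0 is shared.

The *cohort* generator enables perfusion by default (parenchyma f = 0.20,
lesion f = 0.05, D* = 20e-3 mm²/s): pancreatic parenchyma is well perfused
and PDAC hypovascular, and this asymmetric low-b contamination is what makes
computed b=1000 images gain contrast over acquired b=600 beyond pure
noise-averaging — the fit sees the steeper early decay of parenchyma and
extrapolates it down. With these defaults the synthetic contrast ratios land
in the clinically reported regime (CR ≈ 1.6 at acquired b600 rising to
≈ 2.3–2.5 at computed b1000 in the high-resolution geometry).

## Phantom and acquisition

The digital abdomen is a curved parenchyma band (half-width 11 mm, half-
thickness 9 mm, quadratic centreline) with an embedded ellipsoidal lesion,
a thin duct running parallel to the centreline, and a background body
ellipse; no anatomical realism beyond labelled compartments is attempted.
Proximal/distal parenchyma sub-labels split the band at the lesion's
position along the gland axis. Coordinates: 0-based voxel indices, world mm
through an axis-aligned affine, grid centred on the origin, axial slices on
the third axis.

Two geometries mirror a two-protocol abdominal exam: full-FOV 3×3×4 mm
voxels (420×363 mm in-plane → the 140×121 reconstruction matrix; the
acquired 370 mm phase FOV is rounded to the matrix so voxels tile exactly)
and reduced-FOV 2.5×2.5×3 mm over 300×300 mm (120×120). Acquisition
protocols carry b-values (averages): 0 (1), 50 (1), 300 (2), 600 (5), plus
b = 1000 (11) in the reduced-FOV protocol, with scan times 270 s, 198 s and
900 s.

Simulation steps, in physical order:

1. **Partial volume / PSF.** Tissue occupancy masks are blurred in-plane
   with a Gaussian of FWHM 7 mm (full-FOV) or 3 mm (reduced-FOV) — an
   *effective* point-spread width standing in for the voxel footprint plus
   EPI readout and residual respiratory blur, larger for the conventional
   geometry. Signal mixes linearly across sub-voxel compartments. The bare
   `simulate_dwi` default applies no blur.
2. **Rician noise.** Per excitation, independent Gaussian noise of SD σ is
   added to both quadrature channels and the magnitude taken; the NSA
   excitations of each b-value are averaged as magnitudes, preserving the
   Rician floor. Default per-excitation σ: 50 (full-FOV) vs 52
   (reduced-FOV) on S0 ≈ 1000 — smaller voxels buy resolution with noise.
   Acquired b=1000 images get a noise multiplier of 1.8, modelling the
   motion sensitivity of strong diffusion gradients; this reproduces the
   observation that the *computed* 1000 image has higher apparent SNR than
   the *acquired* one.

## Cohort generator (the study conditions)

Per patient: S0 ~ N(1000, 80); parenchyma ADC ~ N(1.8e-3, 0.12e-3); lesion
ADC ~ N(1.2e-3, 0.10e-3) redrawn until it sits at least 0.2e-3 mm²/s below
the parenchyma (generator contract); lesion diameter ~ U(5, 12) mm — the
small-tumor regime where high-resolution imaging matters and where the
coarse geometry's partial volume bites; lesion position varies ±15 mm along
the gland and ±2 mm across slices. Each patient is imaged by both
protocols on the same world-space anatomy. All randomness flows from
explicit seeds; identical seeds give bit-identical outputs.

Two simulation routes share this model: the image route rasterizes whole
volumes and runs the full fit → computed-DWI → ROI chain; the sparse route
evaluates the identical signal, noise and per-voxel fit only at ROI voxels
(lesion partial volume via the exact Marcum-Q mass of the PSF inside the
lesion disc; duct and band-edge spill neglected, as ROIs are placed away
from both). The sparse route exists so that thousand-replicate experiments
(test calibration, agreement calibration) fit in minutes; the two routes
agree on the contrast scale (checked in the suite).

## Fitting and computed DWI

Default fit: log-linear ordinary least squares over b = 0/50/300/600 —
the stated input set of the computed-DWI tool being emulated; WLS (weights
∝ S², the first-order correction for log-transform noise shaping) and a
Gauss–Newton nonlinear LS are options, since vendor tools are black boxes.
Samples at or below `min_signal` (default 1e-6) are excluded from the log;
voxels with fewer than two usable samples are masked invalid (ADC 0,
S0 = first-b signal, computed output 0). Fitted decay rates are clamped to
[0, 4e-3] mm²/s: negative slopes become ADC 0 so computed images can never
grow with b. No spatial regularization or denoising, and no multi-
compartment fitting — the computed image is deliberately the plain
mono-exponential extrapolation, including whatever bias perfusion
contamination induces (that bias is a *feature* under study, quantifiable
by toggling the cohort's perfusion fractions).

## ROIs and metrics

ROIs are in-plane discs (default diameter 5 mm) on the slice nearest their
centre; a voxel belongs to the ROI when its centre lies within the radius,
with the nearest voxel guaranteed so the set is never empty. The tumor ROI
sits at the lesion centre, parenchyma ROIs along the gland on either side;
if a rasterized ROI touches a wrong tissue label it is re-centred to the
nearest pure position (a deterministic surrogate for the reader's manual
correction). ROI statistics use the population-SD convention (divide by n);
the choice is immaterial for paired comparisons but fixed for
reproducibility.

aSNR and aCNR divide by the SD of a parenchyma reference ROI — "apparent"
noise, as estimated in tissue rather than background air. The module
default reference is the proximal ROI; the *study pipeline* defaults to the
pooled proximal+distal sample, because a 5-mm disc on the 3-mm full-FOV
grid rasterizes to 1–4 voxels and a single-voxel ROI has SD 0 (aSNR
undefined); pooling doubles the sample and makes the estimate usable at
every patient. Undefined metrics raise an explicit error, never a silent
infinity.

A consequence worth knowing: with 2–10 voxels behind each SD, aSNR/aCNR are
heavy-tailed ratio estimates. Cohort *means* of these metrics are unstable
in a way that has nothing to do with the underlying effect, so directional
claims are evaluated as paired-majority signs (the statistic a signed-rank
test responds to), and the null-calibration experiments show the Wilcoxon
on CR running slightly above its nominal 5% level (pooled rate ≈ 5.3%,
with single comparisons reaching ~6–7% in some replicate blocks) — an
artifact of ratio-metric asymmetry at these ROI sizes, documented rather
than hidden (the aCNR tests calibrate within the binomial band).

## Reader panel

Each item maps a latent variable through three fixed cutpoints with
independent per-reader Gaussian jitter (cumulative-threshold ordinal
model): image quality ← log aSNR minus a per-dataset artifact penalty
(computed images carry a misregistration penalty, the full-FOV geometry a
distortion/motion penalty); lesion detection ← aCNR; DWI
signal-intensity type ← CR with *descending* coding (type 1 = clear
hyperintensity … type 4 = hypointense). Two aspects were calibrated by
Monte-Carlo against the agreement target: the jitters (0.005 / 0.015 /
0.0025 on the respective latent scales), and the cutpoint placement — each
dataset's latent distribution must keep a ≥15–20% minority category,
because a near-unanimous category lets a single split rating collapse
Fleiss' κ toward 0 (the prevalence paradox), which no jitter level fixes.
With the defaults the weakest item×dataset κ stays in the almost-perfect
band ([0.81, 1.00]) in >99% of 46-patient cohorts (mean weakest-κ ≈ 0.94).
`default_rating_model("low")` triples the jitter for sensitivity analyses.

## Statistics

Wilcoxon signed-rank: zero differences dropped (Wilcoxon's original
convention; Pratt handling switchable), tied absolute differences
mid-ranked, two-sided throughout. The exact null enumerates all sign flips
of the observed (doubled) mid-ranks by dynamic programming — identical to
brute-force 2ⁿ enumeration, tie-safe, and cheap far beyond the n ≤ 25
auto-mode cutoff; above it the tie-corrected normal approximation (no
continuity correction, matching the common asymptotic form) is used.
Friedman uses within-subject mid-ranks with the tie-correction factor
1 − ΣT/(nk(k²−1)); Dunn–Bonferroni compares mean within-subject ranks with
SE = √(k(k+1)/(6n)) and multiplies two-sided p by the number of pairs.
Fleiss' κ follows the standard P̄/P̄e definitions (statsmodels under the
hood) with the published interpretation bands; negative κ is reported in
the "slight" band with a warning, and the all-raters-one-category
degenerate case returns κ = 1 flagged. Normality screening defaults to
Lilliefors (estimated moments; table p-values clipped to [0.001, 0.2]),
with the plain KS variant available. Significance is p ≤ 0.05, inclusive.

## Problem sizes and reproducibility

Replicated experiments run at reduced sizes chosen to keep the full suite
in minutes while preserving the estimands: direction reproduction uses 100
image-route cohorts of 46 patients on 64×64×8 grids (native voxel sizes,
smaller matrices); null calibration uses 1000 sparse-route cohorts;
agreement calibration 150–200. Single-phantom identities run at the full
120×120×20 reduced-FOV grid. `scripts/acceptance.py --seed N --out f.json`
recomputes everything from one seed.

## What passing tests do and do not show

The generator emulates the *mechanisms* the clinical comparison invokes —
mono-exponential decay with perfusion contamination, resolution-dependent
partial volume, Rician averaging, protocol timing — under idealized
conditions: no geometric distortion, no misregistration between b-values
(its image-quality effect enters only through the reader model's artifact
penalties), no susceptibility or motion artifacts, piecewise-homogeneous
tissues, and reader behaviour reduced to a one-dimensional latent per item.
Passing the suite therefore shows that the *pipeline* is correct and that
the qualitative orderings follow from the stated physics at the stated
parameters; it does not reproduce, and cannot validate, the numeric tables
of any patient study. Tissue parameters are calibration choices, not
measurements.
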