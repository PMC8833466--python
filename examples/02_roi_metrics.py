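"""Place the study's 5-mm ROIs on a phantom and compute aSNR / aCNR / CR.

On a noiseless equal-S0 phantom the contrast ratio follows the closed form
CR(b) = exp((ADC_parenchyma - ADC_lesion) * b), so the printed values land
exactly on e^0.36 at b=600 and e^0.6 at the computed b=1000.
"""

import numpy as np

import pancdwi as p
from pancdwi.cohort import place_study_rois
from pancdwi.roi import propagate_roi, roi_stats

phantom = p.make_phantom(p.RFOV, lesion_diameter_mm=14.0)
stack = p.simulate_dwi(phantom, p.RFOV_PROTOCOL_600, noise_sigma=0.0, seed=0)
fit = p.fit_monoexponential(stack)
c1000 = p.compute_dwi(fit, 1000.0).signal

# tumor + proximal/distal parenchyma ROIs from phantom ground truth,
# rasterized on the defining (b600) grid and copied to the computed volume
rois = place_study_rois(phantom)
for role, roi in rois.items():
    vox = propagate_roi(roi, phantom.geometry, phantom.geometry)
    print(f"{role:22s} centre {np.round(roi.center_mm, 1)} -> {len(vox)} voxels")

# noiseless volumes have zero ROI SD (aSNR/aCNR deliberately undefined),
# so report the contrast ratio of means directly
for name, vol in (("acquired b600", stack.volume(600.0)), ("computed b1000", c1000)):
    stats = {k: roi_stats(vol, propagate_roi(r, phantom.geometry, phantom.geometry))
             for k, r in rois.items()}
    cr = stats["tumor"].mean_si / stats["parenchyma_proximal"].mean_si
    print(f"{name}: CR_proximal = {cr:.6f}")

print("expected: e^0.36 = %.6f, e^0.6 = %.6f" % (np.exp(0.36), np.exp(0.6)))
print("the lesion/parenchyma ratio grows as exp(0.6e-3 * b): higher computed "
      "b-values buy contrast at no scan-time cost")

# with noise, aSNR falls at the computed high b while aCNR rises
noisy = p.simulate_dwi(phantom, p.RFOV_PROTOCOL_600, noise_sigma=52.0, seed=3)
nfit = p.fit_monoexponential(noisy)
for name, vol in (("acquired b600", noisy.volume(600.0)),
                  ("computed b1000", p.compute_dwi(nfit, 1000.0).signal)):
    stats = {k: roi_stats(vol, propagate_roi(r, phantom.geometry, phantom.geometry))
             for k, r in rois.items()}
    rec = p.compute_metrics(stats["tumor"], stats["parenchyma_proximal"],
                            stats["parenchyma_distal"], reference="pooled", dataset_id=name)
    print(f"{name}: aSNR = {rec.asnr:6.2f}  aCNR = {rec.acnr:6.2f}")
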