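"""Build a digital pancreas phantom, simulate a DWI acquisition, and
synthesize a computed b=1000 image from the b<=600 data.

The printed numbers show the core identity of computed DWI: on noiseless
mono-exponential data the extrapolated volume equals the analytic decay, so
any error is pure floating-point round-off.
"""

import numpy as np

import pancdwi as p

# a 120x120x20 reduced-FOV phantom (2.5 x 2.5 x 3 mm voxels, 300 mm FOV)
phantom = p.make_phantom(p.RFOV, lesion_diameter_mm=14.0)
print("grid:", phantom.label_map.shape)
print("lesion ADC %.1e, parenchyma ADC %.1e mm^2/s" % (
    phantom.tissue("lesion").adc, phantom.tissue("parenchyma_proximal").adc))

# noiseless acquisition at b = 0/50/300/600 with the protocol's averaging
stack = p.simulate_dwi(phantom, p.RFOV_PROTOCOL_600, noise_sigma=0.0, seed=0)

# voxel-wise log-linear fit and extrapolation to b = 1000
fit = p.fit_monoexponential(stack, b_subset=(0.0, 50.0, 300.0, 600.0))
cdwi = p.compute_dwi(fit, 1000.0)

analytic = p.noiseless_signal(phantom, [1000.0])[..., 0]
m = analytic > 0
max_rel = np.max(np.abs(cdwi.signal[m] - analytic[m]) / analytic[m])
print("max relative error of computed b=1000 vs analytic: %.2e" % max_rel)
print("(noiseless extrapolation is exact: the log of a mono-exponential is linear)")

# the same pipeline with Rician noise: ADC maps recover the tissue values
noisy = p.simulate_dwi(phantom, p.RFOV_PROTOCOL_600, noise_sigma=20.0, seed=1)
nfit = p.fit_monoexponential(noisy)
par = phantom.label_map == p.LABELS["parenchyma_proximal"]
print("median fitted parenchyma ADC at S0/sigma=50: %.4e (truth 1.8e-3)"
      % np.median(nfit.adc_map[par]))
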