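"""Three-phase demodulation and reflectance-standard calibration.

Renders a noiseless raw image stack through a vignette-like gain field,
demodulates the three-phase triplets, and calibrates against a co-imaged
reference standard — showing that the system gain cancels and the absolute
diffuse reflectance of the tissue is recovered.
"""

import numpy as np

from sfdikit import (
    AcquisitionConfig,
    CalibrationConfig,
    calibrate,
    default_phantom_spec,
    demodulate,
    generate_phantom_truth,
    render_raw_stack,
    render_reference_stack,
)
from sfdikit.light_transport import forward_rd
from sfdikit.synthetic import smooth_gain_field
import dataclasses

acq = AcquisitionConfig()
spec = dataclasses.replace(default_phantom_spec(seed=1), noise_sigma=0.0)
truth = generate_phantom_truth(spec)
gain = smooth_gain_field(truth.labels.shape, np.random.default_rng(2), amplitude=0.3)

cal = CalibrationConfig(reference_mua=np.full(4, 0.0045), reference_musp=np.full(4, 1.1))
tissue = demodulate(render_raw_stack(truth, acq, spec, gain=gain))
reference = demodulate(render_reference_stack(
    acq, cal.reference_mua, cal.reference_musp, truth.labels.shape, gain=gain))

refl = calibrate(tissue, reference, cal)
freqs = np.asarray(acq.frequencies)
rd_true = forward_rd(truth.mua[:, None], truth.musp[:, None], freqs[None, :, None, None])
err = np.max(np.abs(refl.rd - rd_true) / rd_true)

print(f"gain field spans {gain.min():.2f}-{gain.max():.2f} (30% vignette)")
print(f"calibrated reflectance error vs truth: {err:.2e} relative")
print(f"R_d at f=0 averages {refl.rd[:, 0].mean():.3f}; at f=0.33 mm^-1 it falls to "
      f"{refl.rd[:, -1].mean():.3f}")
print("The illumination/collection gain cancels exactly in the tissue/standard ratio;")
print("frequency-dependent attenuation of the envelope carries the optical information.")
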