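"""Decompose per-wavelength optical properties into tissue parameters.

Chromophore unmixing (non-negative least squares over oxy-/deoxy-hemoglobin
and water) and the scattering power law recover the five spectral parameters
from four-wavelength absorption and scattering spectra.
"""

import numpy as np

from sfdikit import fit_chromophores, fit_scattering, load_default_basis
from sfdikit.spectral import derived_hemoglobin, forward_mua

basis = load_default_basis()
wl = basis.wavelengths

# a tissue-like truth: 14 uM HbO2, 6 uM Hb, 35% water
mua = forward_mua(14.0, 6.0, 0.35, basis)
print("mu_a spectrum (mm^-1):", np.round(mua, 5))
c_hbo2, c_hb, water = fit_chromophores(mua, basis)
hbt, o2 = derived_hemoglobin(c_hbo2, c_hb)
print(f"recovered: HbO2 {c_hbo2:.2f} uM, Hb {c_hb:.2f} uM "
      f"-> HbT {hbt:.1f} uM, %O2 {o2:.1f}, %H2O {100*water:.1f}")

musp = 1.2 * (wl / 800.0) ** -0.9
a, b = fit_scattering(musp, wl)
print(f"scattering power law: A {a:.3f} mm^-1 at 800 nm, slope b {b:.3f}")
print("A tracks scatterer density; a larger b means more Rayleigh-like (smaller)")
print("scatterers — the axis along which stroma and epithelium separate.")
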