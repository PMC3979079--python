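# NIR chromophore basis at the four acquisition wavelengths.
# eps_* are molar extinction coefficients converted from the standard public
# hemoglobin compilation (Prahl, cm^-1/M) via mm^-1 uM^-1 = 2.3026e-7 * eps[cm^-1/M];
# mua_water is the pure-water absorption coefficient (Segelstein compilation), rounded.
# units: nm, mm^-1 uM^-1, mm^-1 uM^-1, mm^-1
wavelength_nm,eps_hbo2,eps_hb,mua_water
658,7.368e-05,7.431e-04,3.6e-04
730,8.980e-05,2.538e-04,1.9e-03
850,2.436e-04,1.591e-04,4.3e-03
970,2.726e-04,1.612e-04,4.5e-02
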