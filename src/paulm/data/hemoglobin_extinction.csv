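# Molar extinction coefficients of human hemoglobin in water (cm^-1 M^-1),
# from the widely used OMLC/Prahl compilation of tabulated spectra.
wavelength_nm,eps_hbo2,eps_hb
700,290.0,1794.28
750,518.0,1405.24
800,816.0,761.72
850,1058.0,691.32
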