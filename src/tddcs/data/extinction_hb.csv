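# Hemoglobin extinction coefficients, natural-log convention, 1/(cm*uM).
# Compiled literature values (standard tabulated in-vitro spectra), converted
# from base-10 molar extinction e (1/(cm*M)) as e * ln(10) * 1e-6.
# Replaceable: pass a custom ChromophoreBasis to use a different source.
wavelength_nm,HbO2,HHb
685,0.0006678,0.0050199
785,0.0016253,0.0024717
830,0.0022428,0.0015958
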