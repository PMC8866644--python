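# Decadic molar extinction coefficients of human hemoglobin, cm^-1 (mol/L)^-1.
# Compiled spectrophotometric values (Prahl compilation, OMLC); widely used in
# continuous-wave NIRS processing. Selected by table id "prahl_760_850".
wavelength_nm	eps_oxy	eps_deoxy
760	586.0	1548.52
850	1058.0	691.32
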