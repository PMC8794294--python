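# Molar extinction coefficients for hemoglobin, cm^-1 / (mol/L).
# Compiled continuous-wave NIRS values (Prahl / Cope compilation) at the
# two acquisition wavelengths.  version: 1
wavelength_nm	eps_hbo2	eps_hbr
690	276.0	2051.96
830	974.0	693.04
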