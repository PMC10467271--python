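# Molar extinction coefficients of hemoglobin in water, standard tabulated
# compilation (oxy- and deoxyhemoglobin), units: cm^-1 / (mol/L).
wavelength_nm,eps_hbo,eps_hbr
690,276.0,2051.96
730,446.0,1102.2
760,586.0,1548.52
780,710.0,1075.44
808,856.6,736.8
830,974.0,693.04
850,1058.0,691.32
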