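wavelength_nm,eps_hb,eps_hbo2
755,1551.0,555.2
1064,134.0,867.0
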