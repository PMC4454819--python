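ligand,sasa,sasa_over_polar,refractivity,band_gap
MEE,344.15,5.04,31.78,-211.8
MEEE,438.46,5.66,42.82,-211.7
TMAT,286.83,7.39,48.38,-215.8
MES,314.97,3.02,28.01,-195.3
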