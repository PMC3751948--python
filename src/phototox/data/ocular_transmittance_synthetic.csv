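# synthetic stand-in anchor table for ocular media transmittance
# (dimensionless); interpolated monotonically by the loader
wavelength_nm,value
380,0.02
390,0.05
400,0.12
410,0.25
420,0.38
430,0.47
440,0.53
450,0.575
460,0.6
470,0.62
480,0.64
490,0.655
500,0.665
520,0.68
550,0.7
600,0.72
650,0.735
700,0.75
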