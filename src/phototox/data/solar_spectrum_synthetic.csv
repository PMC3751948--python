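# synthetic stand-in emulating the shape of a ground-level
# direct+circumsolar solar spectral irradiance (W/m^2/nm)
wavelength_nm,value
380,0.7277
385,0.7672
390,0.8058
395,0.8434
400,0.8800
405,0.9155
410,0.9499
415,0.9830
420,1.0149
425,1.0456
430,1.0749
435,1.1030
440,1.1297
445,1.1551
450,1.1792
455,1.2020
460,1.2234
465,1.2436
470,1.2624
475,1.2800
480,1.2964
485,1.3116
490,1.3255
495,1.3383
500,1.3500
505,1.3606
510,1.3701
515,1.3785
520,1.3860
525,1.3925
530,1.3981
535,1.4027
540,1.4065
545,1.4095
550,1.4116
555,1.4130
560,1.4137
565,1.4137
570,1.4129
575,1.4116
580,1.4096
585,1.4071
590,1.4039
595,1.4003
600,1.3962
605,1.3916
610,1.3865
615,1.3810
620,1.3752
625,1.3689
630,1.3623
635,1.3554
640,1.3481
645,1.3406
650,1.3328
655,1.3247
660,1.3164
665,1.3079
670,1.2991
675,1.2902
680,1.2811
685,1.2719
690,1.2625
695,1.2529
700,1.2433
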