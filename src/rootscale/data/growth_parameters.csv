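genotype,r_tap_linear,r_lateral_linear,r_tap_exp,r_lateral_exp,nob_tap,nob_lateral
Estonia1,0.59,0.64,1.65,0.36,131.5,13.0
Estonia2,1.30,0.89,2.25,0.48,130.4,19.5
Estonia3,1.25,0.62,1.10,0.35,105.2,18.7
Estonia4,0.97,0.70,2.03,0.38,67.1,10.6
Latvia1,1.08,0.86,1.95,0.41,109.1,30.0
Latvia2,1.14,1.05,1.92,0.54,50.6,41.3
Latvia3,1.07,0.64,1.34,0.35,135.4,24.2
Latvia4,1.46,0.81,1.82,0.36,128.0,35.0
Norway1,1.28,0.42,1.31,0.26,134.6,20.8
Norway2,0.85,0.43,1.03,0.38,152.6,31.3
Portugal1,0.51,0.59,1.65,0.35,140.0,22.7
Portugal2,0.95,0.69,1.39,0.38,90.0,23.2
Portugal3,1.18,0.66,1.62,0.27,58.6,26.8
Portugal4,0.77,0.69,1.94,0.39,151.8,8.4
Sweden1,1.20,0.92,2.50,0.52,106.0,38.7
Sweden2,0.97,0.77,1.57,0.43,74.2,7.0
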