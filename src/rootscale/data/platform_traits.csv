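genotype,tap_seedling_cm,tap_mature_cm,lateral_seedling_cm,lateral_mature_cm,ln_seedling_cm,ln_seedling_first_segment_cm,ln_mature_cm,ln_mature_first_segment_cm
Estonia1,9.1,44.7,0.1,782.9,0.34,0.14,0.80,0.19
Estonia2,12.8,70.4,97.1,3114.2,0.54,0.17,0.70,0.14
Estonia3,7.7,74.7,51.2,1326.4,0.71,0.30,1.07,0.13
Estonia4,11.6,47.0,57.6,623.2,0.70,0.18,0.94,0.26
Latvia1,11.5,63.3,73.9,4072.7,0.58,0.19,0.80,0.22
Latvia2,10.9,36.4,69.5,3069.7,0.72,0.18,0.60,0.13
Latvia3,8.8,79.9,44.4,2872.4,0.59,0.19,0.71,0.23
Latvia4,11.1,52.5,96.6,5080.4,0.41,0.11,0.37,0.11
Norway1,8.5,49.8,46.4,2354.1,0.37,0.12,0.44,0.12
Norway2,6.6,58.0,34.4,2462.0,0.38,0.17,0.78,0.12
Portugal1,8.9,49.0,69.4,1685.2,0.35,0.11,0.73,0.13
Portugal2,8.5,46.8,51.8,1817.6,0.52,0.16,0.70,0.17
Portugal3,9.5,40.4,42.7,2260.7,0.69,0.24,0.51,0.11
Portugal4,10.8,77.4,65.0,764.8,0.51,0.14,0.96,0.15
Sweden1,13.5,49.8,120.2,4699.0,0.47,0.12,0.72,0.21
Sweden2,9.5,49.7,48.3,277.9,0.67,0.24,1.80,0.53
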