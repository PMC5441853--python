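genotype,onset_dag,peak_dag,fit_r2,fit_p
Estonia1,34,41.3,0.97,0.0009
Estonia2,34,49.1,0.70,0.0488
Estonia3,38,44.3,0.93,0.0045
Estonia4,31,36.7,0.82,0.0143
Latvia1,48,58.5,0.97,0.0002
Latvia2,42,50.8,0.76,0.0547
Latvia3,42,55.8,0.93,0.0014
Latvia4,38,50.6,0.76,0.0288
Norway1,42,50.3,0.73,0.0370
Norway2,31,41.4,0.98,0.0001
Portugal1,31,37.8,0.70,0.0276
Portugal2,34,40.8,0.71,0.0459
Portugal3,38,41.6,0.97,0.0002
Portugal4,31,33.5,0.91,0.0027
Sweden1,34,53.1,0.70,0.0502
Sweden2,31,38.0,0.72,0.0419
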