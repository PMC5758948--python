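run_id,bgp_ml_per_gvs,bmp_ml_per_gvs,cods_removal_pct
1,44.34,37.87,36.35
2,47.6,41.83,36.4
3,48.65,42.03,35.18
4,42.68,36.35,33.26
5,40.3,35.7,35.89
6,38.56,31.86,38.12
7,24.6,18.96,48.41
8,28.1,21.81,37.81
9,42.93,36.83,37.75
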