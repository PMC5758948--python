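run_id,response,mean,sd
1,bgp_ml_per_gvs,167.39,16.92
2,bgp_ml_per_gvs,240.01,5.25
3,bgp_ml_per_gvs,270.99,7.87
4,bgp_ml_per_gvs,136.28,3.18
5,bgp_ml_per_gvs,104.02,5.83
6,bgp_ml_per_gvs,86.54,10.15
7,bgp_ml_per_gvs,17.07,0.92
8,bgp_ml_per_gvs,25.55,1.51
9,bgp_ml_per_gvs,140.11,0.31
1,bmp_ml_per_gvs,79.58,8.85
2,bmp_ml_per_gvs,124.09,6.84
3,bmp_ml_per_gvs,126.78,6.74
4,bmp_ml_per_gvs,67.76,9.21
5,bmp_ml_per_gvs,61.64,5.35
6,bmp_ml_per_gvs,41.11,6.77
7,bmp_ml_per_gvs,9.34,1.73
8,bmp_ml_per_gvs,13.62,3.16
9,bmp_ml_per_gvs,69.98,4.79
1,cods_removal_pct,68.81,11.96
2,cods_removal_pct,69.85,13.16
3,cods_removal_pct,57.69,3.19
4,cods_removal_pct,-123.25,12.96
5,cods_removal_pct,-81.33,25.72
6,cods_removal_pct,80.57,0.4
7,cods_removal_pct,-263.42,0.0
8,cods_removal_pct,-91.95,29.89
9,cods_removal_pct,77.44,4.03
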