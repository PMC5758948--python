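replicate,bgp_ml_per_gvs,bmp_ml_per_gvs,cods_removal_pct
1,298.23,151.95,70.12
2,275.15,147.21,66.54
3,310.89,156.68,74.0
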