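run_id,A_level,B_level,C_level,D_level,designation,orww_pct,temp_c,sonication_min,ts_pct
1,1,1,1,1,A1B1C1D1,33,36,15,6
2,2,1,2,3,A2B1C2D3,44,36,30,18
3,2,2,3,1,A2B2C3D1,44,46,0,6
4,1,2,2,2,A1B2C2D2,33,46,30,11
5,3,3,2,1,A3B3C2D1,55,56,30,6
6,3,2,1,3,A3B2C1D3,55,46,15,18
7,1,3,3,3,A1B3C3D3,33,56,0,18
8,2,3,1,2,A2B3C1D2,44,56,15,11
9,3,1,3,2,A3B1C3D2,55,36,0,11
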