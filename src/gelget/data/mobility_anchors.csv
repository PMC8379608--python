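gel_fraction_pct,pulse_duration_s,mobility_m2_per_Vs
0.35,0.0002,2e-09
0.35,0.001,1e-08
0.35,0.005,2.4e-08
0.35,0.01,2.8e-08
3.0,0.0002,3e-10
3.0,0.001,3e-10
3.0,0.005,3e-10
3.0,0.01,3e-10
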