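gel_fraction_pct,D_cm2_per_s
0.0,5e-08
0.35,3e-08
3.0,1e-10
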