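slope	intercept	r_squared	n_points	r2_ci_low	r2_ci_high
1.6555816464	0.288155398287	0.622988145235	3	0.622988145235	1
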