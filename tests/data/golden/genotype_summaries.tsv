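genotype	n_traces	n_traces_with_bursts	burst_duration_ms	burst_duration_sd_ms	burst_frequency_hz	firing_rate_hz	ap_count_per_burst	ap_frequency_per_burst_hz
mut_long	12	12	571.868275821	288.490508651	0.386111111111	8.68518518519	22.4752481004	39.8897889439
wt_ref	13	13	167.642681347	50.2235587086	0.47264957265	6.42905982906	13.5896018331	81.9127520312
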