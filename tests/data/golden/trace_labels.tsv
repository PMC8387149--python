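trace_id	genotype	mean_burst_duration_ms	label
wt_ref_00	wt_ref	167.082800812	normal
wt_ref_01	wt_ref	172.804798951	normal
wt_ref_02	wt_ref	175.945898297	elongated
wt_ref_03	wt_ref	171.770251705	normal
wt_ref_04	wt_ref	165.195459612	normal
wt_ref_05	wt_ref	168.592843749	normal
wt_ref_06	wt_ref	162.118242669	normal
wt_ref_07	wt_ref	160.879619124	normal
wt_ref_08	wt_ref	167.920394123	normal
wt_ref_09	wt_ref	161.88975883	normal
wt_ref_10	wt_ref	167.607401487	normal
wt_ref_11	wt_ref	173.901639025	normal
wt_ref_12	wt_ref	163.645749132	normal
mut_long_00	mut_long	590.315264932	elongated
mut_long_01	mut_long	550.340680632	elongated
mut_long_02	mut_long	592.636325851	elongated
mut_long_03	mut_long	584.168642289	elongated
mut_long_04	mut_long	569.362022781	elongated
mut_long_05	mut_long	578.404768498	elongated
mut_long_06	mut_long	542.687297609	elongated
mut_long_07	mut_long	621.38297675	elongated
mut_long_08	mut_long	584.933206922	elongated
mut_long_09	mut_long	552.411227314	elongated
mut_long_10	mut_long	539.52117562	elongated
mut_long_11	mut_long	556.255720655	elongated
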