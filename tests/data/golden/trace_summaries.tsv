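trace_id	genotype	n_bursts	mean_burst_duration_ms	sd_burst_duration_ms	burst_frequency_hz	firing_rate_hz	mean_spikes_per_burst	mean_ap_frequency_per_burst_hz
wt_ref_00	wt_ref	86	167.082800812	53.9282373988	0.477777777778	6.61666666667	13.8488372093	83.2110807216
wt_ref_01	wt_ref	86	172.804798951	54.2760166401	0.477777777778	6.52777777778	13.6279069767	79.9063583433
wt_ref_02	wt_ref	81	175.945898297	60.1281236615	0.45	6.41111111111	14.2469135802	81.945236444
wt_ref_03	wt_ref	82	171.770251705	47.0107297667	0.455555555556	6.43333333333	14.1097560976	83.1120211576
wt_ref_04	wt_ref	91	165.195459612	45.1416124461	0.505555555556	6.8	13.4395604396	82.5809201174
wt_ref_05	wt_ref	87	168.592843749	54.0742566572	0.483333333333	6.52222222222	13.4827586207	80.762870144
wt_ref_06	wt_ref	89	162.118242669	52.3167825959	0.494444444444	6.56666666667	13.2696629213	83.0436796616
wt_ref_07	wt_ref	85	160.879619124	38.5538854436	0.472222222222	6.21111111111	13.1294117647	82.1410201303
wt_ref_08	wt_ref	84	167.920394123	52.1139839893	0.466666666667	6.40555555556	13.7023809524	82.8664121131
wt_ref_09	wt_ref	81	161.88975883	43.637590221	0.45	5.92777777778	13.1604938272	82.3670767169
wt_ref_10	wt_ref	89	167.607401487	44.2895736091	0.494444444444	6.63888888889	13.404494382	80.5023137753
wt_ref_11	wt_ref	85	173.901639025	49.2808598105	0.472222222222	6.67222222222	14.1176470588	81.7831092486
wt_ref_12	wt_ref	80	163.645749132	58.1546109715	0.444444444444	5.84444444444	13.125	80.6436778323
mut_long_00	mut_long	70	590.315264932	290.609941385	0.388888888889	9.18888888889	23.6	40.4216480531
mut_long_01	mut_long	69	550.340680632	268.355081317	0.383333333333	8.23333333333	21.4347826087	39.7558337663
mut_long_02	mut_long	67	592.636325851	267.762502161	0.372222222222	8.67222222222	23.2835820896	39.437447279
mut_long_03	mut_long	71	584.168642289	271.888996357	0.394444444444	9.25	23.4225352113	40.6190565099
mut_long_04	mut_long	69	569.362022781	256.4114559	0.383333333333	8.31666666667	21.6811594203	39.2101807813
mut_long_05	mut_long	69	578.404768498	258.509645598	0.383333333333	8.61666666667	22.4637681159	38.8811415176
mut_long_06	mut_long	72	542.687297609	289.566174171	0.4	8.58888888889	21.4722222222	40.3410686108
mut_long_07	mut_long	69	621.38297675	307.024175018	0.383333333333	9.45555555556	24.652173913	40.4223632319
mut_long_08	mut_long	69	584.933206922	348.314670996	0.383333333333	8.75	22.7826086957	39.5702354365
mut_long_09	mut_long	69	552.411227314	334.014128529	0.383333333333	8.33333333333	21.7101449275	40.1375495483
mut_long_10	mut_long	70	539.52117562	301.116972139	0.388888888889	8.2	21.0857142857	39.5541170292
mut_long_11	mut_long	70	556.255720655	268.312360235	0.388888888889	8.61666666667	22.1142857143	40.3268255635
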