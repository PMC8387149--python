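comparison_id	assay	group_a	group_b	n_a	n_b	mean_difference	ci_low	ci_high	cohens_d	percent_change	n_boot	seed	ci_method
eshock_bs_strong	eshock	ctrl	bs_strong	25	25	259.950768672	221.740057957	325.49698022	2.86414700633	266.19386348	5000	7	bca
eshock_bs_mild	eshock	ctrl	bs_mild	25	25	61.4125753961	46.5726173653	76.5223202888	2.17397834993	62.8874874824	5000	7	bca
eshock_hs_severe	eshock	hs_ctrl	hs_severe	20	20	117.049531568	84.143139633	160.582248958	1.88071221067	114.614753671	5000	7	bca
vortex_bs_strong	vortex	ctrl	bs_strong	25	25	160.224807861	143.523677528	180.218719405	4.81191783513	3103.74739195	5000	7	bca
vortex_bs_mild	vortex	ctrl	bs_mild	25	25	69.0386362607	61.161449652	77.1189693864	4.61861631032	1337.36148664	5000	7	bca
heat_hs_severe	heat	hs_ctrl	hs_severe	20	20	286.650036882	234.201421619	351.080615248	2.88863253966	6608.35724558	5000	7	bca
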