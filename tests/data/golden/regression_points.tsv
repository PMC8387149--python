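genotype	control	x_assay	y_assay	x_cohens_d	y_cohens_d
bs_mild	ctrl	eshock	vortex	2.17397834993	4.61861631032
bs_strong	ctrl	eshock	vortex	2.86414700633	4.81191783513
hs_severe	hs_ctrl	eshock	heat	1.88071221067	2.88863253966
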