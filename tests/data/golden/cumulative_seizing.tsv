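genotype	time_s	fraction_seizing
hs_ctrl	10	0
hs_ctrl	20	0
hs_ctrl	30	0
hs_ctrl	40	0
hs_ctrl	50	0
hs_ctrl	60	0
hs_ctrl	70	0
hs_ctrl	80	0
hs_ctrl	90	0
hs_ctrl	100	0
hs_ctrl	110	0.05
hs_ctrl	120	0.05
hs_severe	10	0
hs_severe	20	0.05
hs_severe	30	0.1
hs_severe	40	0.35
hs_severe	50	0.5
hs_severe	60	0.75
hs_severe	70	0.85
hs_severe	80	0.95
hs_severe	90	0.95
hs_severe	100	0.95
hs_severe	110	1
hs_severe	120	1
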