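genotype	n_classifiable	n_unclassifiable	n_elongated	fraction_elongated
mut_long	12	0	12	1
wt_ref	13	0	1	0.0769230769231
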