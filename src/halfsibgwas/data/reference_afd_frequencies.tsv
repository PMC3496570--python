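marker	trait	freq_elite	freq_average	afd_reported
NIBP_PPC	PPC	0.65	0.29	0.36
GC_NPFFR2_upstream_SCS	SCS	0.64	0.27	0.37
BTA18_multitrait	NM	0.53	0.05	0.48
X_gene_desert_PPC	PPC	0.53	0.02	0.51
X_SSB_pair	SSB	0.58	0.18	0.40
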