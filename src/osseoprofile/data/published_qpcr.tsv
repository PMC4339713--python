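gene_id	timepoint	rnaseq_log2	realtime_pcr
ANGPT4	1w	2.22	1.76
ANGPT4	4w	3.29	1.52
PDGFRA	1w	1.98	3.39
PDGFRA	4w	1.27	0.74
PIP4K2A	1w	1.09	1.98
PIP4K2A	4w	1.57	1.20
WISP2	1w	3.11	1.65
WISP2	4w	2.62	4.06
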