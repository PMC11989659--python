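cdna_hgvs	ag	al	dg	dl	ag_pos	al_pos	dg_pos	dl_pos	maxent_ref	maxent_var	delta_maxent	prior_severe
c.6006-3C>A	0	0.42	0	0		-3					-3.702	0
c.4253+5G>A	0	0	0	0.44				5			-4.809	1
c.1937+392G>A	0	0.01	0	0		-4						0
c.2160+782T>C	0	0	0	0								0
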