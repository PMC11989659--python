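patient_id	cdna_hgvs	protein_hgvs	genomic_region	zygosity	novel
1	c.5554del	p.Gln1852ArgfsTer3		het	1
1	c.260dup	p.Gly88ArgfsTer11		het	0
2	c.6006-3C>A			hom	0
3	c.4853G>A	p.Trp1618Ter		het	0
3			chr1:94480267-94482198del	het	1
4	c.1378del	p.Val460Ter		het	1
4	c.71G>A	p.Arg24His		het	0
5	c.4253+5G>A			het	0
5	c.3172G>T	p.Glu1058Ter		het	1
5	c.1531C>T	p.Arg511Cys		het	0
6	c.4217A>G	p.His1406Arg		hom	0
7	c.4217A>G	p.His1406Arg		het	0
7	c.1561del	p.Val521SerfsTer47		het	0
8	c.5761G>A	p.Val1921Met		het	0
8	c.1804C>T	p.Arg602Trp		het	0
9	c.2894A>G	p.Asn965Ser		het	0
9	c.2424C>G	p.Tyr808Ter		het	0
10	c.5646G>A	p.Met1882Ile		het	0
10	c.1761-2A>G			het	0
11	c.1006del	p.Ser336ProfsTer38		het	0
11	c.303-2A>G			het	0
12	c.2894A>G	p.Asn965Ser		het	0
12	c.1222C>T	p.Arg408Ter		het	0
13	c.3385C>T	p.Arg1129Cys		het	0
13	c.858+2T>A			het	0
14	c.2894A>G	p.Asn965Ser		het	0
14	c.1531C>T	p.Arg511Cys		het	0
15	c.2919-1G>A			hom	1
16	c.42C>A	p.Asn14Lys		het	0
16	c.1937+392G>A			het	1
17	c.6119G>A	p.Arg1040Gln		het	0
17	c.2160+782T>C			het	1
18	c.6689del	p.Leu2230ProfsTer17		het	1
18	c.2633C>A	p.Ser878Ter		het	0
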