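"""Parse HGVS variant notation and infer consequence classes.

Each line prints a variant's normalized form and the consequence class
the pipeline assigns it: protein notation dominates when present, and
otherwise the intron offset decides between canonical-splice (+/-1,2),
near-splice (within 20 nt) and deep intronic.
"""

from abca4tools import parse_variant

EXAMPLES = [
    dict(cdna_hgvs="c.71G>A", protein_hgvs="p.Arg24His"),
    dict(cdna_hgvs="c.4853G>A", protein_hgvs="p.Trp1618Ter"),
    dict(cdna_hgvs="c.5554del", protein_hgvs="p.Gln1852ArgfsTer3"),
    dict(cdna_hgvs="c.2919-1G>A"),
    dict(cdna_hgvs="c.4253+5G>A"),
    dict(cdna_hgvs="c.1937+392G>A"),
    dict(genomic_region="chr1:94480267-94482198del"),
]

for fields in EXAMPLES:
    v = parse_variant(**fields)
    print(f"{v.format():45s} -> {v.consequence.value}")
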