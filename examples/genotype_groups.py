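"""Assign genotype groups A/B/C from classified alleles.

Two missense alleles give group A; one null allele plus a missense gives
B; two null (or splice-loss) alleles give C.  A homozygous variant
counts as two alleles.
"""

from abca4tools import (
    Consequence,
    Zygosity,
    assign_allele_severity,
    assign_genotype_group,
)

cases = {
    "two het missense": [
        (Consequence.MISSENSE, Zygosity.HET),
        (Consequence.MISSENSE, Zygosity.HET)],
    "het nonsense + het missense": [
        (Consequence.NONSENSE, Zygosity.HET),
        (Consequence.MISSENSE, Zygosity.HET)],
    "homozygous canonical splice": [
        (Consequence.CANONICAL_SPLICE, Zygosity.HOM)],
    "nonsense + frameshift + missense": [
        (Consequence.NONSENSE, Zygosity.HET),
        (Consequence.FRAMESHIFT, Zygosity.HET),
        (Consequence.MISSENSE, Zygosity.HET)],
}

for label, alleles in cases.items():
    classified = [(assign_allele_severity(c), z) for c, z in alleles]
    a = assign_genotype_group(classified)
    print(f"{label:35s} -> group {a.group.value} "
          f"({a.n_deleterious_alleles} deleterious, {a.n_mild_alleles} mild)")
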