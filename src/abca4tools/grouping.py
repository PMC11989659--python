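"""Allele deleteriousness and patient genotype groups A/B/C.

A variant allele is *deleterious* (severe) when it belongs to the ACMG
null-variant class — nonsense, frameshift, canonical +/-1 or 2
splice-site change, initiation-codon loss, or single/multi-exon deletion
— or when it is a non-canonical intronic variant with a predicted splice
gain/loss or prior literature evidence of a severe phenotype.  Missense
and in-frame indel alleles are non-deleterious (mild) for grouping
purposes.

Patients carrying two or more alleles are then assigned a genotype
group in the Fujinami scheme:

* **A** — two or more missense / in-frame (non-deleterious) alleles;
* **B** — exactly one deleterious allele alongside one or more
  non-deleterious alleles;
* **C** — two or more deleterious alleles.

A homozygous variant contributes two alleles.  Phase is not modelled;
grouping uses allele counts only, as in the source classification.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

from .hgvs import Consequence
from .splice import SpliceCall

__all__ = [
    "Zygosity",
    "SeverityBasis",
    "AlleleCategory",
    "AlleleSeverity",
    "GenotypeGroup",
    "GenotypeAssignment",
    "MissingSpliceEvidenceError",
    "assign_allele_severity",
    "assign_genotype_group",
    "NULL_VARIANT_CONSEQUENCES",
]

#: Consequence classes in the ACMG null-variant (PVS1-class) category.
NULL_VARIANT_CONSEQUENCES = frozenset({
    Consequence.NONSENSE,
    Consequence.FRAMESHIFT,
    Consequence.CANONICAL_SPLICE,
    Consequence.START_LOSS,
    Consequence.CNV_DELETION,
})

_INTRONIC_PREDICTION_DEPENDENT = frozenset({
    Consequence.NEAR_SPLICE_INTRONIC,
    Consequence.DEEP_INTRONIC,
})


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"

    @property
    def allele_count(self) -> int:
        return 2 if self is Zygosity.HOM else 1


class AlleleCategory(str, enum.Enum):
    DELETERIOUS = "deleterious"
    NON_DELETERIOUS = "non_deleterious"


class SeverityBasis(str, enum.Enum):
    NULL_VARIANT_CLASS = "null_variant_class"
    SPLICE_PREDICTION = "splice_prediction"
    PRIOR_PHENOTYPE_EVIDENCE = "prior_phenotype_evidence"
    MISSENSE_OR_INFRAME = "missense_or_inframe"
    #: non-canonical intronic variant with no supporting splice evidence
    DEEP_INTRONIC_UNSUPPORTED = "deep_intronic_unsupported"


@dataclass(frozen=True)
class AlleleSeverity:
    category: AlleleCategory
    basis: SeverityBasis

    @property
    def is_deleterious(self) -> bool:
        return self.category is AlleleCategory.DELETERIOUS


class GenotypeGroup(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GenotypeAssignment:
    group: GenotypeGroup
    n_deleterious_alleles: int
    n_mild_alleles: int

    @property
    def total_alleles(self) -> int:
        return self.n_deleterious_alleles + self.n_mild_alleles


class MissingSpliceEvidenceError(ValueError):
    """A near-splice intronic variant has no splice-score row.

    Raised loudly because the resulting allele category changes the
    patient's genotype group.
    """


def assign_allele_severity(
    consequence: Consequence,
    splice_call: Optional[SpliceCall] = None,
    prior_severe: bool = False,
) -> AlleleSeverity:
    """Classify one variant allele as deleterious or non-deleterious.

    Null-class consequences are deleterious outright.  Non-canonical
    intronic variants are deleterious when the splice prediction calls a
    site gain/loss or when prior phenotype evidence exists; otherwise
    they are non-deleterious.  A near-splice variant with no splice-score
    row raises :class:`MissingSpliceEvidenceError`; a deep-intronic one
    defaults to non-deleterious (unsupported), since hundreds of
    nucleotides from the splice site there is no functional-site score
    to be missing.
    """
    if consequence in NULL_VARIANT_CONSEQUENCES:
        return AlleleSeverity(AlleleCategory.DELETERIOUS,
                              SeverityBasis.NULL_VARIANT_CLASS)
    if consequence in _INTRONIC_PREDICTION_DEPENDENT:
        if splice_call is not None and splice_call.is_effect:
            return AlleleSeverity(AlleleCategory.DELETERIOUS,
                                  SeverityBasis.SPLICE_PREDICTION)
        if prior_severe:
            return AlleleSeverity(AlleleCategory.DELETERIOUS,
                                  SeverityBasis.PRIOR_PHENOTYPE_EVIDENCE)
        if splice_call is None and consequence is Consequence.NEAR_SPLICE_INTRONIC:
            raise MissingSpliceEvidenceError(
                "near-splice intronic variant has no splice-score row; "
                "its classification would change the genotype group"
            )
        return AlleleSeverity(AlleleCategory.NON_DELETERIOUS,
                              SeverityBasis.DEEP_INTRONIC_UNSUPPORTED)
    if consequence in (Consequence.MISSENSE, Consequence.INFRAME_INDEL):
        return AlleleSeverity(AlleleCategory.NON_DELETERIOUS,
                              SeverityBasis.MISSENSE_OR_INFRAME)
    # 'other' (e.g. synonymous or unannotated exonic): not deleterious
    return AlleleSeverity(AlleleCategory.NON_DELETERIOUS,
                          SeverityBasis.MISSENSE_OR_INFRAME)


def assign_genotype_group(
    alleles: Sequence[Tuple[AlleleSeverity, Zygosity]],
) -> GenotypeAssignment:
    """Assign a genotype group from classified alleles.

    Homozygous entries count twice.  Two or more deleterious alleles give
    group C; exactly one deleterious plus at least one non-deleterious
    gives B; no deleterious allele but at least two alleles gives A.
    Fewer than two alleles in total leaves the patient unassigned.
    """
    if not alleles:
        raise ValueError("cannot assign a genotype group from an empty allele list")
    n_del = sum(z.allele_count for sev, z in alleles if sev.is_deleterious)
    n_mild = sum(z.allele_count for sev, z in alleles if not sev.is_deleterious)
    total = n_del + n_mild
    if total < 2:
        group = GenotypeGroup.UNASSIGNED
    elif n_del >= 2:
        group = GenotypeGroup.C
    elif n_del == 1:
        group = GenotypeGroup.B
    else:
        group = GenotypeGroup.A
    return GenotypeAssignment(group=group, n_deleterious_alleles=n_del,
                              n_mild_alleles=n_mild)
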