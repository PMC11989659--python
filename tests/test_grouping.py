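"""Allele deleteriousness rules and genotype-group assignment."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from abca4tools import (
    AlleleCategory,
    AlleleSeverity,
    Consequence,
    DeltaChannel,
    GenotypeGroup,
    MissingSpliceEvidenceError,
    SeverityBasis,
    SplicePrediction,
    Zygosity,
    assign_allele_severity,
    assign_genotype_group,
    call_splice_effect,
)

DEL = AlleleSeverity(AlleleCategory.DELETERIOUS, SeverityBasis.NULL_VARIANT_CLASS)
MILD = AlleleSeverity(AlleleCategory.NON_DELETERIOUS,
                      SeverityBasis.MISSENSE_OR_INFRAME)
HET, HOM = Zygosity.HET, Zygosity.HOM


def _loss_call():
    return call_splice_effect(
        SplicePrediction(delta_scores={DeltaChannel.ACCEPTOR_LOSS: 0.42}),
    )


def _no_effect_call():
    return call_splice_effect(
        SplicePrediction(delta_scores={DeltaChannel.ACCEPTOR_LOSS: 0.01}),
    )


@pytest.mark.parametrize("consequence", [
    Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.CANONICAL_SPLICE,
    Consequence.START_LOSS, Consequence.CNV_DELETION,
])
def test_null_class_variants_are_deleterious(consequence):
    sev = assign_allele_severity(consequence)
    assert sev.is_deleterious and sev.basis is SeverityBasis.NULL_VARIANT_CLASS


@pytest.mark.parametrize("consequence", [
    Consequence.MISSENSE, Consequence.INFRAME_INDEL,
])
def test_missense_and_inframe_are_non_deleterious(consequence):
    sev = assign_allele_severity(consequence)
    assert not sev.is_deleterious
    assert sev.basis is SeverityBasis.MISSENSE_OR_INFRAME


def test_intronic_with_predicted_loss_is_deleterious():
    sev = assign_allele_severity(Consequence.NEAR_SPLICE_INTRONIC, _loss_call())
    assert sev.is_deleterious and sev.basis is SeverityBasis.SPLICE_PREDICTION


def test_intronic_with_prior_phenotype_evidence_is_deleterious():
    sev = assign_allele_severity(Consequence.NEAR_SPLICE_INTRONIC,
                                 _no_effect_call(), prior_severe=True)
    assert sev.is_deleterious
    assert sev.basis is SeverityBasis.PRIOR_PHENOTYPE_EVIDENCE


def test_deep_intronic_without_support_is_non_deleterious():
    sev = assign_allele_severity(Consequence.DEEP_INTRONIC, _no_effect_call())
    assert not sev.is_deleterious
    assert sev.basis is SeverityBasis.DEEP_INTRONIC_UNSUPPORTED
    # with no score row at all, deep intronic still defaults to unsupported
    assert not assign_allele_severity(Consequence.DEEP_INTRONIC).is_deleterious


def test_near_splice_without_score_row_errors():
    with pytest.raises(MissingSpliceEvidenceError):
        assign_allele_severity(Consequence.NEAR_SPLICE_INTRONIC)


@pytest.mark.parametrize(
    "alleles, expected",
    [
        # two het missense -> A
        ([(MILD, HET), (MILD, HET)], GenotypeGroup.A),
        # het nonsense + het missense -> B
        ([(DEL, HET), (MILD, HET)], GenotypeGroup.B),
        # homozygous canonical-splice deleterious -> C
        ([(DEL, HOM)], GenotypeGroup.C),
        # het deleterious x2 + het missense (triallelic) -> C
        ([(DEL, HET), (DEL, HET), (MILD, HET)], GenotypeGroup.C),
        # homozygous missense -> A
        ([(MILD, HOM)], GenotypeGroup.A),
        # single het allele -> unassigned
        ([(DEL, HET)], GenotypeGroup.UNASSIGNED),
        ([(MILD, HET)], GenotypeGroup.UNASSIGNED),
    ],
)
def test_genotype_group_assignment(alleles, expected):
    assignment = assign_genotype_group(alleles)
    assert assignment.group is expected
    assert assignment.total_alleles == sum(z.allele_count for _, z in alleles)


def test_empty_allele_list_errors():
    with pytest.raises(ValueError):
        assign_genotype_group([])


def _oracle(alleles):
    """Brute-force truth table written directly from the three group clauses."""
    n_del = sum(2 if z is HOM else 1 for sev, z in alleles if sev.is_deleterious)
    n_mild = sum(2 if z is HOM else 1 for sev, z in alleles
                 if not sev.is_deleterious)
    if n_del + n_mild < 2:
        return GenotypeGroup.UNASSIGNED
    if n_del >= 2:
        return GenotypeGroup.C
    if n_del == 1 and n_mild >= 1:
        return GenotypeGroup.B
    if n_del == 0 and n_mild >= 2:
        return GenotypeGroup.A
    raise AssertionError("unreachable")  # pragma: no cover


def test_exhaustive_equivalence_with_truth_table():
    """The classifier agrees with the clause-by-clause oracle over every
    multiset of up to four alleles x {deleterious, mild} x {het, hom}."""
    options = [(sev, zyg) for sev in (DEL, MILD) for zyg in (HET, HOM)]
    n_cases = 0
    for length in range(1, 5):
        for combo in itertools.combinations_with_replacement(options, length):
            assignment = assign_genotype_group(list(combo))
            assert assignment.group is _oracle(list(combo)), combo
            n_cases += 1
    assert n_cases == sum(1 for length in range(1, 5)
                          for _ in itertools.combinations_with_replacement(
                              options, length))


_ORDER = {GenotypeGroup.A: 0, GenotypeGroup.B: 1, GenotypeGroup.C: 2}


@given(alleles=st.lists(st.tuples(st.booleans(), st.sampled_from([HET, HOM])),
                        min_size=1, max_size=5),
       index=st.integers(min_value=0, max_value=4))
def test_promoting_an_allele_never_moves_group_toward_a(alleles, index):
    """Monotonicity: turning any allele deleterious never lowers the group
    in the severity order A < B < C."""
    index %= len(alleles)
    base = [(DEL if d else MILD, z) for d, z in alleles]
    promoted = list(base)
    promoted[index] = (DEL, promoted[index][1])
    g0 = assign_genotype_group(base).group
    g1 = assign_genotype_group(promoted).group
    if g0 in _ORDER and g1 in _ORDER:
        assert _ORDER[g1] >= _ORDER[g0]


def test_cohort_groups_match_printed_labels(fixture_result, printed_groups):
    """End to end on the packaged cohort: every patient's computed group
    equals the table's printed group, giving counts A=5, B=6, C=7."""
    for pid, printed in printed_groups.items():
        assert fixture_result.assignments[pid].group.value == printed, pid
    assert fixture_result.summary.group_counts == {"A": 5, "B": 6, "C": 7}
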