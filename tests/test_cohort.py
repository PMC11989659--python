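"""Cohort summary statistics, variant spectrum and region tallies."""

import statistics

import pytest

from abca4tools import (
    GeneModel,
    PatientRecord,
    PipelineConfig,
    VisualAcuity,
    Zygosity,
    fixture_path,
    occurrence_count,
    parse_variant,
    read_gene_model,
    region_tally,
    round_half_up,
    summarize_cohort,
    variant_spectrum,
)


def _patient(pid="P1", onset=50.0, od=0.5, os=0.5, **kwargs):
    return PatientRecord(
        id=pid, sex="F", onset_age=onset, exam_age=onset + 1,
        acuity_od=VisualAcuity(str(od), od), acuity_os=VisualAcuity(str(os), os),
        **kwargs)


def test_single_patient_summary():
    summary = summarize_cohort([_patient()], {})
    assert summary.n_adult == 1 and summary.n_child == 0
    assert summary.onset_mean_adult == 50
    assert summary.onset_mean_child is None  # empty stratum absent, not zero
    assert summary.mean_logmar_od == 0.5


def test_empty_cohort_errors():
    with pytest.raises(ValueError):
        summarize_cohort([], {})


def test_counts_are_conserved(fixture_result):
    s = fixture_result.summary
    assert s.n_adult + s.n_child == s.n_patients == 18
    assert sum(s.group_percent.values()) == pytest.approx(100.0)
    assert sum(s.af_counts.values()) == s.n_with_af
    assert sum(s.zygosity_counts.values()) == s.n_patients
    assert s.n_severity_classified + s.n_unclassifiable == s.n_patients
    for g, row in s.crosstab.items():
        assert sum(row.values()) <= s.group_counts[g]


def test_group_bcva_equals_brute_force_eye_mean(fixture_result):
    """The group BCVA statistic equals a direct mean over all member eyes."""
    s = fixture_result.summary
    for g, stats in s.group_stats.items():
        eyes = [e for p in fixture_result.patients
                if fixture_result.assignments[p.id].group.value == g
                for e in (p.acuity_od.logmar, p.acuity_os.logmar)]
        assert stats.bcva_mean == pytest.approx(statistics.fmean(eyes))
        assert stats.n_eyes == len(eyes)
        # and equals the patient-weighted mean of per-patient eye means
        per_patient = [
            (p.acuity_od.logmar + p.acuity_os.logmar) / 2
            for p in fixture_result.patients
            if fixture_result.assignments[p.id].group.value == g]
        assert stats.bcva_mean == pytest.approx(statistics.fmean(per_patient))


def test_group_central_values(fixture_result):
    s = fixture_result.summary
    assert round_half_up(s.group_stats["A"].onset_mean, 1) == 39.4
    assert round_half_up(s.group_stats["B"].onset_mean, 1) == 18.5
    assert round_half_up(s.group_stats["C"].onset_mean, 1) == 10.4
    assert (s.group_stats["B"].onset_min, s.group_stats["B"].onset_max) == (6, 55)
    assert (s.group_stats["C"].onset_min, s.group_stats["C"].onset_max) == (7, 25)


def test_variant_spectrum_empty():
    assert variant_spectrum([]) == ({}, 0, 0)


def test_spectrum_deduplicates_by_normalized_string():
    v1 = parse_variant(cdna_hgvs="c.2894A>G", protein_hgvs="p.Asn965Ser")
    v2 = parse_variant(cdna_hgvs=" c.2894A>G ", protein_hgvs="p.Asn965Ser")
    spectrum, n_novel, n_distinct = variant_spectrum([v1, v2])
    assert spectrum == {"missense": 1} and n_distinct == 1


def test_occurrence_count(fixture_result):
    patients = fixture_result.patients
    assert occurrence_count(patients, "c.2894A>G") == 3
    assert occurrence_count(patients, "c.2894A>G", count_alleles=True) == 3
    # homozygote: one occurrence, two alleles
    assert occurrence_count(patients, "c.2919-1G>A") == 1
    assert occurrence_count(patients, "c.2919-1G>A", count_alleles=True) == 2
    assert occurrence_count(patients, "c.9999G>A") == 0


# ---------------------------------------------------------------------------
# gene model and region tallies


@pytest.fixture
def toy_model():
    return GeneModel(
        transcript="toy",
        exons=((1, 1, 100), (2, 101, 200)),
        domains=(("ECD1", 1, 500),),
    )


def test_gene_model_validation():
    with pytest.raises(ValueError):
        GeneModel("bad", exons=((1, 1, 100), (2, 150, 200)))
    with pytest.raises(ValueError):
        GeneModel("bad", exons=((1, 1, 100),),
                  domains=(("D1", 1, 50), ("D2", 40, 80)))


def test_region_tally_on_toy_model(toy_model):
    variants = [
        parse_variant(cdna_hgvs="c.150G>A", protein_hgvs="p.Arg24His"),
        parse_variant(cdna_hgvs="c.100+5G>A"),
        parse_variant(cdna_hgvs="c.50del", protein_hgvs="p.Gly17AlafsTer4"),
    ]
    tally = region_tally(variants, toy_model)
    assert tally.exon_counts == {1: 1, 2: 1}
    assert tally.intron_counts == {1: 1}
    assert tally.domain_counts == {"ECD1": 2}
    assert tally.unlocatable == []


def test_region_tally_unlocatable(toy_model):
    variants = [
        parse_variant(cdna_hgvs="c.999G>A", protein_hgvs="p.Arg333His"),
        parse_variant(genomic_region="chr1:100-200del"),
    ]
    tally = region_tally(variants, toy_model)
    assert tally.n_located == 0
    assert sorted(tally.unlocatable) == ["c.999G>A", "chr1:100-200del"]


def test_region_tally_on_cohort_with_synthetic_model(fixture_result):
    """Every cDNA-addressable cohort variant lands in exactly one exon or
    intron of the synthetic transcript model; only the CNV is unlocatable."""
    model = read_gene_model(fixture_path("synthetic_gene_model.json"))
    variants = [v for p in fixture_result.patients for v, _ in p.alleles]
    tally = region_tally(variants, model)
    assert tally.n_located == 29
    assert tally.unlocatable == ["chr1:94480267-94482198del"]
    assert sum(tally.intron_counts.values()) == 8  # intronic variants
    assert sum(tally.exon_counts.values()) == 21


def test_round_half_up():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(44.333, 1) == 44.3
    assert round_half_up(0.9183, 2) == 0.92
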