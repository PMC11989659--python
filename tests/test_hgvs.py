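"""HGVS parsing, round-tripping and consequence inference."""

import pandas as pd
import pytest

from abca4tools import (
    Consequence,
    HgvsParseError,
    fixture_path,
    infer_consequence,
    parse_cdna,
    parse_genomic_region,
    parse_protein,
    parse_variant,
)
from abca4tools.hgvs import EditKind


@pytest.mark.parametrize(
    "text, anchor, offset, kind, ref, alt",
    [
        ("c.71G>A", 71, 0, EditKind.SUBSTITUTION, "G", "A"),
        ("c.1937+392G>A", 1937, 392, EditKind.SUBSTITUTION, "G", "A"),
        ("c.6006-3C>A", 6006, -3, EditKind.SUBSTITUTION, "C", "A"),
        ("c.5554del", 5554, 0, EditKind.DELETION, "", ""),
        ("c.260dup", 260, 0, EditKind.DUPLICATION, "", ""),
        ("c.2919-1G>A", 2919, -1, EditKind.SUBSTITUTION, "G", "A"),
        ("c.100_102del", 100, 0, EditKind.DELETION, "", ""),
        ("c.100_101insATG", 100, 0, EditKind.INSERTION, "", "ATG"),
    ],
)
def test_parse_cdna(text, anchor, offset, kind, ref, alt):
    c = parse_cdna(text)
    assert (c.anchor_position, c.intron_offset, c.edit_kind) == (anchor, offset, kind)
    assert (c.ref_allele, c.alt_allele) == (ref, alt)


@pytest.mark.parametrize(
    "text, ref, num, alt, fs, ter",
    [
        ("p.Arg24His", "Arg", 24, "His", False, None),
        ("p.Val460Ter", "Val", 460, "Ter", False, None),
        ("p.Leu2230ProfsTer17", "Leu", 2230, "Pro", True, 17),
        ("p.Gln1852ArgfsTer3", "Gln", 1852, "Arg", True, 3),
        ("p.(Asn965Ser)", "Asn", 965, "Ser", False, None),
    ],
)
def test_parse_protein(text, ref, num, alt, fs, ter):
    p = parse_protein(text)
    assert (p.ref_residue, p.residue_number, p.alt_residue) == (ref, num, alt)
    assert (p.frameshift, p.fs_ter_distance) == (fs, ter)


def test_parse_genomic_region():
    g = parse_genomic_region("chr1:94480267-94482198del")
    assert (g.chromosome, g.start, g.end) == ("chr1", 94480267, 94482198)
    assert g.operation == "deletion"


@pytest.mark.parametrize(
    "parser, text",
    [
        (parse_cdna, "g.123A>T"),
        (parse_cdna, "c.12X>Y"),
        (parse_cdna, "c.100_102inv"),
        (parse_cdna, "c.0A>T"),
        (parse_cdna, "c.100AA>T"),
        (parse_protein, "p.12Arg"),
        (parse_protein, "p.Xyz24His"),
        (parse_genomic_region, "chr1:200-100del"),
        (parse_genomic_region, "chr1:100-200dup"),
    ],
)
def test_malformed_inputs_fail_loudly(parser, text):
    with pytest.raises(HgvsParseError):
        parser(text)


def test_whitespace_and_unicode_dash_invariance():
    plain = parse_cdna("c.6006-3C>A")
    assert parse_cdna(" c.6006−3C>A ") == plain  # unicode minus
    assert parse_cdna("c.6006–3C>A") == plain    # en dash


@pytest.mark.parametrize(
    "fields, expected",
    [
        (dict(protein_hgvs="p.Trp1618Ter", cdna_hgvs="c.4853G>A"),
         Consequence.NONSENSE),
        (dict(cdna_hgvs="c.2919-1G>A"), Consequence.CANONICAL_SPLICE),
        (dict(cdna_hgvs="c.2160+782T>C"), Consequence.DEEP_INTRONIC),
        (dict(cdna_hgvs="c.4253+5G>A"), Consequence.NEAR_SPLICE_INTRONIC),
        (dict(genomic_region="chr1:94480267-94482198del"),
         Consequence.CNV_DELETION),
        (dict(cdna_hgvs="c.71G>A", protein_hgvs="p.Arg24His"),
         Consequence.MISSENSE),
        (dict(cdna_hgvs="c.5554del", protein_hgvs="p.Gln1852ArgfsTer3"),
         Consequence.FRAMESHIFT),
        # deletion whose protein effect is a direct stop: protein dominates
        (dict(cdna_hgvs="c.1378del", protein_hgvs="p.Val460Ter"),
         Consequence.NONSENSE),
        (dict(cdna_hgvs="c.1A>G", protein_hgvs="p.Met1Val"),
         Consequence.START_LOSS),
        # exonic ranged indels without protein annotation: frame decides
        (dict(cdna_hgvs="c.100_102del"), Consequence.INFRAME_INDEL),
        (dict(cdna_hgvs="c.100_103del"), Consequence.FRAMESHIFT),
    ],
)
def test_infer_consequence(fields, expected):
    assert parse_variant(**fields).consequence is expected


def test_near_splice_window_is_configurable():
    assert parse_variant(cdna_hgvs="c.4253+5G>A",
                         near_splice_window=4).consequence \
        is Consequence.DEEP_INTRONIC
    with pytest.raises(ValueError):
        infer_consequence(parse_cdna("c.4253+5G>A"), near_splice_window=2)


def test_unclassifiable_variant_errors():
    with pytest.raises(HgvsParseError):
        parse_variant()


def test_roundtrip_idempotent_on_cohort_table():
    """Parsing then re-formatting is idempotent on every cohort variant string."""
    df = pd.read_csv(fixture_path("table1_variants.tsv"), sep="\t",
                     dtype=str, keep_default_na=False)
    assert len(df) == 34  # allele rows across the 18 patients
    for _, row in df.iterrows():
        if row["cdna_hgvs"]:
            once = parse_cdna(row["cdna_hgvs"]).format()
            assert parse_cdna(once).format() == once == row["cdna_hgvs"]
        if row["protein_hgvs"]:
            once = parse_protein(row["protein_hgvs"]).format()
            assert parse_protein(once).format() == once == row["protein_hgvs"]
        if row["genomic_region"]:
            once = parse_genomic_region(row["genomic_region"]).format()
            assert parse_genomic_region(once).format() == once \
                == row["genomic_region"]


def test_cohort_consequence_spectrum(fixture_result):
    """Distinct cohort variants split into the expected consequence classes."""
    spectrum = fixture_result.summary.spectrum
    assert spectrum == {
        "missense": 10,
        "nonsense": 6,
        "frameshift": 5,
        "canonical_splice": 4,
        "near_splice_intronic": 2,
        "deep_intronic": 2,
        "cnv_deletion": 1,
    }
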