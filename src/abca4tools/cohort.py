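"""Cohort-level summary statistics and gene-region tallies.

Everything a genotype–phenotype correlation report needs from a parsed
cohort: onset statistics stratified into childhood/adolescent versus
adult onset, per-eye mean logMAR, autofluorescence-type distribution,
zygosity breakdown, genotype-group counts and per-group central values,
the genotype x severity cross-tabulation, the distinct-variant
consequence spectrum with novelty counts, and counts of variants per
exon, intron and protein domain of a transcript model.

Group-level central values are arithmetic means over the group's
members (BCVA over all eyes of all members); true medians are reported
alongside.  Strata with no members are reported as absent, never as
zero.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .config import SEVERITY_COMPUTED, SEVERITY_FROM_TABLE, PipelineConfig
from .grouping import GenotypeAssignment, GenotypeGroup, Zygosity
from .hgvs import Consequence, VariantDescriptor
from .phenotype import better_eye, classify_severity
from .records import PatientRecord

__all__ = [
    "CohortSummary",
    "GroupStats",
    "GeneModel",
    "RegionTally",
    "round_half_up",
    "summarize_cohort",
    "variant_spectrum",
    "occurrence_count",
    "region_tally",
]


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero, as printed clinical tables do."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _mean(values: Sequence[float]) -> Optional[float]:
    return statistics.fmean(values) if values else None


@dataclass(frozen=True)
class GroupStats:
    """Per-genotype-group onset and BCVA statistics.

    ``bcva_mean`` averages the logMAR of *all eyes* of the group's
    members (two eyes per patient), the convention used for group-level
    acuity in genotype–phenotype reports.
    """

    n: int
    onset_mean: float
    onset_median: float
    onset_min: float
    onset_max: float
    bcva_mean: float
    bcva_median: float
    n_eyes: int


@dataclass
class CohortSummary:
    n_patients: int
    n_adult: int
    n_child: int
    onset_mean_adult: Optional[float]
    onset_mean_child: Optional[float]
    n_late_onset: int
    mean_logmar_od: float
    mean_logmar_os: float
    af_counts: Dict[int, int]
    n_with_af: int
    zygosity_counts: Dict[str, int]
    group_counts: Dict[str, int]
    group_percent: Dict[str, float]
    n_unassigned: int
    group_stats: Dict[str, GroupStats]
    severity_counts: Dict[int, int]
    severity_percent: Dict[int, float]
    n_severity_classified: int
    n_unclassifiable: int
    crosstab: Dict[str, Dict[int, int]]
    spectrum: Dict[str, int]
    n_distinct_variants: int
    n_novel: int

    def to_dict(self) -> dict:
        """JSON-friendly nested dict with deterministic key order."""
        d = {
            "n_patients": self.n_patients,
            "onset": {
                "n_adult": self.n_adult,
                "n_child": self.n_child,
                "mean_adult": self.onset_mean_adult,
                "mean_child": self.onset_mean_child,
                "n_late_onset": self.n_late_onset,
            },
            "bcva": {
                "mean_logmar_od": self.mean_logmar_od,
                "mean_logmar_os": self.mean_logmar_os,
            },
            "af_counts": {str(k): v for k, v in sorted(self.af_counts.items())},
            "n_with_af": self.n_with_af,
            "zygosity_counts": dict(sorted(self.zygosity_counts.items())),
            "groups": {
                "counts": dict(sorted(self.group_counts.items())),
                "percent": dict(sorted(self.group_percent.items())),
                "n_unassigned": self.n_unassigned,
                "stats": {
                    g: {
                        "n": s.n,
                        "onset_central_value_mean": s.onset_mean,
                        "onset_median": s.onset_median,
                        "onset_range": [s.onset_min, s.onset_max],
                        "bcva_central_value_mean": s.bcva_mean,
                        "bcva_median": s.bcva_median,
                        "n_eyes": s.n_eyes,
                    }
                    for g, s in sorted(self.group_stats.items())
                },
            },
            "severity": {
                "counts": {str(k): v for k, v in sorted(self.severity_counts.items())},
                "percent": {str(k): v for k, v in sorted(self.severity_percent.items())},
                "n_classified": self.n_severity_classified,
                "n_unclassifiable": self.n_unclassifiable,
            },
            "crosstab": {
                g: {str(k): v for k, v in sorted(row.items())}
                for g, row in sorted(self.crosstab.items())
            },
            "spectrum": dict(sorted(self.spectrum.items())),
            "n_distinct_variants": self.n_distinct_variants,
            "n_novel": self.n_novel,
        }
        return d


def _severity_for(patient: PatientRecord, config: PipelineConfig) -> Optional[int]:
    if config.severity_source == SEVERITY_FROM_TABLE:
        return patient.severity_label
    assignment = classify_severity(
        patient.onset_age,
        better_eye(patient.acuity_od.logmar, patient.acuity_os.logmar),
        fundus=patient.fundus_type, af=patient.af_type, erg=patient.erg_type,
    )
    return None if assignment.klass is None else int(assignment.klass)


def _zygosity_category(patient: PatientRecord) -> str:
    total = patient.n_alleles
    if total < 2:
        return "single_het"
    if total > 2:
        return "triallelic"
    if patient.is_homozygous:
        return "homozygous"
    return "biallelic_het"


def summarize_cohort(
    patients: Sequence[PatientRecord],
    assignments: Mapping[str, GenotypeAssignment],
    config: PipelineConfig = PipelineConfig(),
) -> CohortSummary:
    """Compute the full cohort summary.

    ``assignments`` maps patient id to its genotype assignment; patients
    without an A/B/C group are excluded from group statistics.  Severity
    classes come from the printed labels or the five-criteria classifier
    according to ``config.severity_source``, and severity-stratified
    fields use evaluable patients only.
    """
    if not patients:
        raise ValueError("cannot summarize an empty cohort")

    adult = [p for p in patients if p.onset_age >= config.adult_onset_threshold]
    child = [p for p in patients if p.onset_age < config.adult_onset_threshold]
    late = [p for p in patients if p.onset_age >= config.late_onset_threshold]

    af_counts: Dict[int, int] = {}
    for p in patients:
        if p.af_type is not None:
            af_counts[p.af_type] = af_counts.get(p.af_type, 0) + 1

    zyg: Dict[str, int] = {}
    for p in patients:
        cat = _zygosity_category(p)
        zyg[cat] = zyg.get(cat, 0) + 1

    group_of: Dict[str, str] = {}
    for p in patients:
        a = assignments.get(p.id)
        if a is not None and a.group in (GenotypeGroup.A, GenotypeGroup.B,
                                         GenotypeGroup.C):
            group_of[p.id] = a.group.value
    group_counts = {g: 0 for g in "ABC"}
    for g in group_of.values():
        group_counts[g] += 1
    n_assigned = sum(group_counts.values())
    group_percent = {g: 100.0 * c / len(patients) for g, c in group_counts.items()}

    group_stats: Dict[str, GroupStats] = {}
    for g in "ABC":
        members = [p for p in patients if group_of.get(p.id) == g]
        if not members:
            continue
        onsets = [p.onset_age for p in members]
        eyes = [e for p in members
                for e in (p.acuity_od.logmar, p.acuity_os.logmar)]
        group_stats[g] = GroupStats(
            n=len(members),
            onset_mean=statistics.fmean(onsets),
            onset_median=statistics.median(onsets),
            onset_min=min(onsets), onset_max=max(onsets),
            bcva_mean=statistics.fmean(eyes),
            bcva_median=statistics.median(eyes),
            n_eyes=len(eyes),
        )

    severity_of: Dict[str, int] = {}
    n_unclassifiable = 0
    for p in patients:
        if not p.evaluable:
            n_unclassifiable += 1
            continue
        klass = _severity_for(p, config)
        if klass is None:
            n_unclassifiable += 1
        else:
            severity_of[p.id] = klass
    severity_counts = {k: 0 for k in (1, 2, 3)}
    for k in severity_of.values():
        severity_counts[k] += 1
    n_classified = sum(severity_counts.values())
    severity_percent = {
        k: (100.0 * c / n_classified if n_classified else 0.0)
        for k, c in severity_counts.items()
    }

    crosstab: Dict[str, Dict[int, int]] = {g: {1: 0, 2: 0, 3: 0} for g in "ABC"}
    for pid, klass in severity_of.items():
        g = group_of.get(pid)
        if g is not None:
            crosstab[g][klass] += 1

    variants = [(v, z) for p in patients for v, z in p.alleles]
    spectrum, n_novel, n_distinct = variant_spectrum(v for v, _ in variants)

    return CohortSummary(
        n_patients=len(patients),
        n_adult=len(adult), n_child=len(child),
        onset_mean_adult=_mean([p.onset_age for p in adult]),
        onset_mean_child=_mean([p.onset_age for p in child]),
        n_late_onset=len(late),
        mean_logmar_od=statistics.fmean(p.acuity_od.logmar for p in patients),
        mean_logmar_os=statistics.fmean(p.acuity_os.logmar for p in patients),
        af_counts=af_counts,
        n_with_af=sum(af_counts.values()),
        zygosity_counts=zyg,
        group_counts=group_counts,
        group_percent=group_percent,
        n_unassigned=len(patients) - n_assigned,
        group_stats=group_stats,
        severity_counts=severity_counts,
        severity_percent=severity_percent,
        n_severity_classified=n_classified,
        n_unclassifiable=n_unclassifiable,
        crosstab=crosstab,
        spectrum=spectrum,
        n_distinct_variants=n_distinct,
        n_novel=n_novel,
    )


def variant_spectrum(
    variants: Iterable[VariantDescriptor],
) -> Tuple[Dict[str, int], int, int]:
    """Distinct-variant consequence spectrum.

    Variants are deduplicated by their normalized cDNA string (genomic
    string for CNVs).  Returns ``(spectrum, n_novel, n_distinct)`` where
    ``spectrum`` maps consequence-class name to distinct-variant count
    and ``n_novel`` counts novel variants among the distinct set.
    """
    distinct: Dict[str, VariantDescriptor] = {}
    for v in variants:
        distinct.setdefault(v.key, v)
    spectrum: Dict[str, int] = {}
    for v in distinct.values():
        name = v.consequence.value
        spectrum[name] = spectrum.get(name, 0) + 1
    n_novel = sum(1 for v in distinct.values() if v.novel)
    return spectrum, n_novel, len(distinct)


def occurrence_count(
    patients: Sequence[PatientRecord],
    target: str,
    count_alleles: bool = False,
) -> int:
    """How often a variant occurs in the cohort.

    By default counts *patients* carrying the variant (a homozygote
    counts once); with ``count_alleles=True`` counts alleles (a
    homozygote counts twice).  ``target`` is matched against normalized
    variant keys, so minor formatting differences do not matter.
    """
    from .hgvs import parse_cdna, parse_genomic_region

    try:
        key = parse_cdna(target).format() if target.strip().startswith("c.") \
            else parse_genomic_region(target).format()
    except Exception:
        key = target.strip()
    total = 0
    for p in patients:
        hits = [(v, z) for v, z in p.alleles if v.key == key]
        if not hits:
            continue
        total += sum(z.allele_count for _, z in hits) if count_alleles else 1
    return total


# ---------------------------------------------------------------------------
# transcript model and region tallies


@dataclass(frozen=True)
class GeneModel:
    """Transcript exon structure in cDNA coordinates plus a domain map.

    ``exons`` is an ordered list of ``(index, cdna_start, cdna_end)``
    with 1-based inclusive, contiguous, non-overlapping intervals; intron
    *i* lies between exons *i* and *i+1*.  ``domains`` maps protein
    residue ranges (1-based inclusive, non-overlapping) to domain names.
    """

    transcript: str
    exons: Tuple[Tuple[int, int, int], ...]
    domains: Tuple[Tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        prev_end = 0
        for idx, start, end in self.exons:
            if start != prev_end + 1 or end < start:
                raise ValueError(
                    f"exon {idx}: cDNA intervals must be contiguous, "
                    f"non-overlapping and ordered (got {start}-{end} after "
                    f"{prev_end})"
                )
            prev_end = end
        spans = sorted((s, e) for _, s, e in self.domains)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("domain residue ranges overlap")

    @property
    def cds_length(self) -> int:
        return self.exons[-1][2]

    @classmethod
    def from_json(cls, text: str) -> "GeneModel":
        obj = json.loads(text)
        return cls(
            transcript=obj["transcript"],
            exons=tuple((e["index"], e["cdna_start"], e["cdna_end"])
                        for e in obj["exons"]),
            domains=tuple((d["name"], d["aa_start"], d["aa_end"])
                          for d in obj.get("domains", [])),
        )

    def exon_of(self, cdna_position: int) -> Optional[int]:
        for idx, start, end in self.exons:
            if start <= cdna_position <= end:
                return idx
        return None

    def domain_of(self, residue: int) -> Optional[str]:
        for name, start, end in self.domains:
            if start <= residue <= end:
                return name
        return None


@dataclass
class RegionTally:
    """Counts of distinct variants per exon, intron and protein domain."""

    exon_counts: Dict[int, int] = field(default_factory=dict)
    intron_counts: Dict[int, int] = field(default_factory=dict)
    domain_counts: Dict[str, int] = field(default_factory=dict)
    unlocatable: List[str] = field(default_factory=list)

    @property
    def n_located(self) -> int:
        return sum(self.exon_counts.values()) + sum(self.intron_counts.values())


def region_tally(
    variants: Iterable[VariantDescriptor],
    model: GeneModel,
) -> RegionTally:
    """Tally distinct variants into exons, introns and protein domains.

    Exonic variants are located by the anchor cDNA position; intronic
    variants fall into the intron adjacent to the exon containing their
    anchor (on the side given by the offset's sign).  Protein domains
    are tallied independently from the protein residue number, where
    present.  Variants whose anchor lies beyond the model span — and
    genomic-only CNVs, which carry no cDNA coordinate — are reported as
    unlocatable.
    """
    distinct: Dict[str, VariantDescriptor] = {}
    for v in variants:
        distinct.setdefault(v.key, v)

    tally = RegionTally()
    n_introns = len(model.exons) - 1
    for key, v in distinct.items():
        if v.cdna is None:
            tally.unlocatable.append(key)
        else:
            exon = model.exon_of(v.cdna.anchor_position)
            if exon is None:
                tally.unlocatable.append(key)
            elif v.cdna.intron_offset == 0:
                tally.exon_counts[exon] = tally.exon_counts.get(exon, 0) + 1
            else:
                intron = exon if v.cdna.intron_offset > 0 else exon - 1
                if 1 <= intron <= n_introns:
                    tally.intron_counts[intron] = \
                        tally.intron_counts.get(intron, 0) + 1
                else:
                    tally.unlocatable.append(key)
        if v.protein is not None:
            domain = model.domain_of(v.protein.residue_number)
            if domain is not None:
                tally.domain_counts[domain] = \
                    tally.domain_counts.get(domain, 0) + 1
    return tally
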