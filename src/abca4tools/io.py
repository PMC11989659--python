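"""Table readers/writers and the end-to-end cohort pipeline.

All tables are tab-separated UTF-8 with "." as the decimal separator and
an empty string for absent fields (TSV rather than CSV, so commas inside
HGVS-adjacent notes never need quoting).  En/em dashes and the Unicode
minus sign, common in text pasted from typeset tables, are normalized to
the ASCII hyphen before HGVS parsing.

The pipeline is deterministic: identical inputs and configuration
produce byte-identical summary JSON (sorted keys, fixed float
formatting).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .cohort import CohortSummary, GeneModel, round_half_up, summarize_cohort
from .config import PipelineConfig
from .grouping import (
    AlleleSeverity,
    GenotypeAssignment,
    MissingSpliceEvidenceError,
    Zygosity,
    assign_allele_severity,
    assign_genotype_group,
)
from .hgvs import Consequence, HgvsParseError, VariantDescriptor, parse_variant
from .phenotype import VisualAcuity, better_eye, classify_severity
from .records import PatientRecord
from .splice import DeltaChannel, SpliceCall, SplicePrediction, call_splice_effect

__all__ = [
    "PipelineError",
    "PipelineResult",
    "read_patient_table",
    "read_variant_table",
    "read_splice_table",
    "read_gene_model",
    "load_fixture_cohort",
    "fixture_path",
    "run_pipeline",
    "validation_report",
    "write_group_table",
    "write_severity_table",
    "summary_to_json",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_PATIENT_COLUMNS = ["patient_id", "sex", "onset_age", "exam_age",
                    "acuity_od", "acuity_os"]
_VARIANT_COLUMNS = ["patient_id", "cdna_hgvs", "protein_hgvs",
                    "genomic_region", "zygosity", "novel"]
_SPLICE_COLUMNS = ["cdna_hgvs", "ag", "al", "dg", "dl"]


class PipelineError(ValueError):
    """A hard input error: malformed table, missing column, broken reference."""


def _read_tsv(path: PathLike, required: Sequence[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PipelineError(
            f"{label} table {path}: missing required column(s) {missing}"
        )
    return df


def _opt_int(text: str, what: str, line: int) -> Optional[int]:
    text = text.strip()
    if not text or text.upper() in ("NA", "N/A"):
        return None
    try:
        return int(text)
    except ValueError:
        raise PipelineError(f"line {line}: invalid {what}: {text!r}") from None


def _opt_float(text: str) -> Optional[float]:
    text = str(text).strip()
    if not text or text.upper() in ("NA", "N/A"):
        return None
    return float(text)


def read_patient_table(
    path: PathLike,
    config: PipelineConfig = PipelineConfig(),
) -> List[PatientRecord]:
    """Read and validate a patient phenotype table.

    Rows violating record invariants (e.g. exam age before onset) are
    rejected with their line numbers collected into one
    :class:`PipelineError`; a missing required column is a hard error
    immediately.
    """
    df = _read_tsv(path, _PATIENT_COLUMNS, "patient")
    records: List[PatientRecord] = []
    errors: List[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            records.append(PatientRecord(
                id=row["patient_id"].strip(),
                sex=row["sex"].strip(),
                onset_age=float(row["onset_age"]),
                exam_age=float(row["exam_age"]),
                acuity_od=VisualAcuity.parse(row["acuity_od"],
                                             config.low_vision_codes),
                acuity_os=VisualAcuity.parse(row["acuity_os"],
                                             config.low_vision_codes),
                fundus_type=_opt_int(row.get("fundus_type", ""), "fundus_type", line),
                af_type=_opt_int(row.get("af_type", ""), "af_type", line),
                erg_type=_opt_int(row.get("erg_type", ""), "erg_type", line),
                severity_label=_opt_int(row.get("severity_label", ""),
                                        "severity_label", line),
                evaluable=row.get("evaluable", "1").strip() != "0",
            ))
        except (ValueError, PipelineError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise PipelineError(
            "patient table has invalid rows:\n  " + "\n  ".join(errors)
        )
    return records


# printed genotype-group labels, when the table carries them (cross-check only)
def read_group_labels(path: PathLike) -> Dict[str, str]:
    df = _read_tsv(path, ["patient_id"], "patient")
    if "group_label" not in df.columns:
        return {}
    return {row["patient_id"].strip(): row["group_label"].strip()
            for _, row in df.iterrows() if row["group_label"].strip()}


def read_variant_table(
    path: PathLike,
    config: PipelineConfig = PipelineConfig(),
) -> Dict[str, List[Tuple[VariantDescriptor, Zygosity]]]:
    """Read a variant table into per-patient (descriptor, zygosity) lists."""
    df = _read_tsv(path, _VARIANT_COLUMNS, "variant")
    out: Dict[str, List[Tuple[VariantDescriptor, Zygosity]]] = {}
    errors: List[str] = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            descriptor = parse_variant(
                cdna_hgvs=row["cdna_hgvs"],
                protein_hgvs=row["protein_hgvs"],
                genomic_region=row["genomic_region"],
                novel=row["novel"].strip() == "1",
                near_splice_window=config.near_splice_window,
            )
            zygosity = Zygosity(row["zygosity"].strip().lower())
        except (HgvsParseError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
            continue
        out.setdefault(row["patient_id"].strip(), []).append((descriptor, zygosity))
    if errors:
        raise PipelineError(
            "variant table has invalid rows:\n  " + "\n  ".join(errors)
        )
    return out


def read_splice_table(path: PathLike) -> Dict[str, SplicePrediction]:
    """Read a splice-score table keyed by normalized cDNA string."""
    df = _read_tsv(path, _SPLICE_COLUMNS, "splice-score")
    out: Dict[str, SplicePrediction] = {}
    for _, row in df.iterrows():
        deltas = {
            DeltaChannel.ACCEPTOR_GAIN: float(row["ag"] or 0.0),
            DeltaChannel.ACCEPTOR_LOSS: float(row["al"] or 0.0),
            DeltaChannel.DONOR_GAIN: float(row["dg"] or 0.0),
            DeltaChannel.DONOR_LOSS: float(row["dl"] or 0.0),
        }
        positions = {}
        for channel, col in ((DeltaChannel.ACCEPTOR_GAIN, "ag_pos"),
                             (DeltaChannel.ACCEPTOR_LOSS, "al_pos"),
                             (DeltaChannel.DONOR_GAIN, "dg_pos"),
                             (DeltaChannel.DONOR_LOSS, "dl_pos")):
            value = _opt_float(row.get(col, ""))
            if value is not None:
                positions[channel] = int(value)
        key = parse_variant(cdna_hgvs=row["cdna_hgvs"]).key
        out[key] = SplicePrediction(
            delta_scores=deltas,
            delta_positions=positions,
            maxent_reference=_opt_float(row.get("maxent_ref", "")),
            maxent_variant=_opt_float(row.get("maxent_var", "")),
            maxent_delta=_opt_float(row.get("delta_maxent", "")),
            prior_severe_phenotype=str(row.get("prior_severe", "0")).strip() == "1",
        )
    return out


def read_gene_model(path: PathLike) -> GeneModel:
    return GeneModel.from_json(Path(path).read_text(encoding="utf-8"))


def fixture_path(name: str) -> Path:
    """Path to a packaged data file."""
    return Path(resources.files("abca4tools.data") / name)


def load_fixture_cohort(
    config: PipelineConfig = PipelineConfig(),
) -> Tuple[List[PatientRecord], Dict[str, List[Tuple[VariantDescriptor, Zygosity]]],
           Dict[str, SplicePrediction]]:
    """Load the packaged 18-patient cohort tables (patients, variants, splice)."""
    patients = read_patient_table(fixture_path("table1_patients.tsv"), config)
    variants = read_variant_table(fixture_path("table1_variants.tsv"), config)
    splice = read_splice_table(fixture_path("table2_splice.tsv"))
    return patients, variants, splice


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    patients: List[PatientRecord]
    assignments: Dict[str, GenotypeAssignment]
    severities: Dict[str, Optional[int]]
    summary: CohortSummary
    audit: List[dict] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return summary_to_json(self.summary, indent=indent)


def summary_to_json(summary: CohortSummary, indent: int = 2) -> str:
    """Deterministic JSON rendering: sorted keys, floats at full precision."""
    return json.dumps(summary.to_dict(), sort_keys=True, indent=indent,
                      allow_nan=False)


def classify_patient_alleles(
    alleles: Sequence[Tuple[VariantDescriptor, Zygosity]],
    splice_map: Mapping[str, SplicePrediction],
    config: PipelineConfig = PipelineConfig(),
) -> List[Tuple[VariantDescriptor, AlleleSeverity, Zygosity, Optional[SpliceCall]]]:
    """Classify each of a patient's alleles as deleterious / non-deleterious."""
    out = []
    for descriptor, zygosity in alleles:
        call: Optional[SpliceCall] = None
        prior = False
        prediction = splice_map.get(descriptor.key)
        if prediction is not None:
            in_site = (descriptor.cdna is not None
                       and descriptor.cdna.is_intronic
                       and abs(descriptor.cdna.intron_offset)
                       <= config.near_splice_window)
            call = call_splice_effect(prediction, config.delta_threshold, in_site)
            prior = prediction.prior_severe_phenotype
        severity = assign_allele_severity(descriptor.consequence, call, prior)
        out.append((descriptor, severity, zygosity, call))
    return out


def run_pipeline(
    patient_table: PathLike,
    variant_table: PathLike,
    splice_table: Optional[PathLike] = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full pipeline from TSV inputs to a cohort summary.

    Raises :class:`PipelineError` on any hard input error, including a
    variant row citing an unknown patient id.
    """
    patients = read_patient_table(patient_table, config)
    if not patients:
        raise PipelineError(f"patient table {patient_table} has no rows")
    variants = read_variant_table(variant_table, config)
    splice_map = read_splice_table(splice_table) if splice_table else {}
    return run_pipeline_from_records(patients, variants, splice_map, config)


def run_pipeline_from_records(
    patients: Sequence[PatientRecord],
    variants: Mapping[str, Sequence[Tuple[VariantDescriptor, Zygosity]]],
    splice_map: Mapping[str, SplicePrediction],
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """As :func:`run_pipeline`, from already-parsed inputs."""
    if not patients:
        raise PipelineError("empty cohort")
    known = {p.id for p in patients}
    orphans = sorted(set(variants) - known)
    if orphans:
        raise PipelineError(
            f"variant table cites unknown patient id(s): {orphans}"
        )

    assignments: Dict[str, GenotypeAssignment] = {}
    severities: Dict[str, Optional[int]] = {}
    audit: List[dict] = []
    for patient in patients:
        alleles = list(variants.get(patient.id, []))
        patient.alleles = [(v, z) for v, z in alleles]
        if alleles:
            try:
                classified = classify_patient_alleles(alleles, splice_map, config)
            except MissingSpliceEvidenceError as exc:
                raise PipelineError(f"patient {patient.id}: {exc}") from exc
            assignment = assign_genotype_group(
                [(sev, z) for _, sev, z, _ in classified])
            assignments[patient.id] = assignment
            for descriptor, severity, zygosity, call in classified:
                audit.append({
                    "patient_id": patient.id,
                    "variant": descriptor.key,
                    "consequence": descriptor.consequence.value,
                    "zygosity": zygosity.value,
                    "category": severity.category.value,
                    "basis": severity.basis.value,
                    "splice_effect": call.effect.value if call else None,
                })
            if assignment.group.value == "unassigned":
                logger.warning(
                    "patient %s: only %d allele(s) detected; excluded from "
                    "group statistics", patient.id, assignment.total_alleles)

        sev = classify_severity(
            patient.onset_age,
            better_eye(patient.acuity_od.logmar, patient.acuity_os.logmar),
            fundus=patient.fundus_type, af=patient.af_type,
            erg=patient.erg_type,
        )
        severities[patient.id] = None if sev.klass is None else int(sev.klass)

    summary = summarize_cohort(list(patients), assignments, config)
    return PipelineResult(patients=list(patients), assignments=assignments,
                          severities=severities, summary=summary, audit=audit)


# ---------------------------------------------------------------------------
# output tables and validation report


def write_group_table(result: PipelineResult, path: PathLike) -> None:
    """Per-patient genotype-group TSV plus nothing else (audit is JSON)."""
    rows = []
    for p in result.patients:
        a = result.assignments.get(p.id)
        rows.append({
            "patient_id": p.id,
            "group": a.group.value if a else "unassigned",
            "n_deleterious": a.n_deleterious_alleles if a else 0,
            "n_mild": a.n_mild_alleles if a else 0,
            "total_alleles": a.total_alleles if a else 0,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_severity_table(result: PipelineResult, path: PathLike,
                         config: PipelineConfig = PipelineConfig()) -> None:
    rows = []
    for p in result.patients:
        sev = classify_severity(
            p.onset_age, better_eye(p.acuity_od.logmar, p.acuity_os.logmar),
            fundus=p.fundus_type, af=p.af_type, erg=p.erg_type)
        rows.append({
            "patient_id": p.id,
            "class": "" if sev.klass is None else int(sev.klass),
            "mild_hits": sev.mild_hits,
            "severe_hits": sev.severe_hits,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def validation_report(
    result: PipelineResult,
    printed_group_labels: Optional[Mapping[str, str]] = None,
    published_stats: Optional[Mapping] = None,
) -> List[str]:
    """Cross-check recomputed values against printed labels and statistics.

    Returns human-readable notes for every disagreement found:
    mismatches between computed genotype groups and the table's printed
    group labels, and recomputed headline statistics that differ from
    the published ones beyond print rounding.  An empty list means full
    agreement.
    """
    notes: List[str] = []
    if printed_group_labels:
        for pid, printed in sorted(printed_group_labels.items()):
            a = result.assignments.get(pid)
            computed = a.group.value if a else "unassigned"
            if computed != printed:
                notes.append(
                    f"patient {pid}: computed group {computed} != printed "
                    f"group {printed}")
    if published_stats:
        s = result.summary
        checks = [
            ("mean logMAR OD", s.mean_logmar_od,
             published_stats.get("mean_logmar_od"), 2),
            ("mean logMAR OS", s.mean_logmar_os,
             published_stats.get("mean_logmar_os"), 2),
            ("adult onset mean", s.onset_mean_adult,
             published_stats.get("onset_mean_adult"), 1),
            ("child onset mean", s.onset_mean_child,
             published_stats.get("onset_mean_child"), 1),
        ]
        for g, stats in s.group_stats.items():
            central = (published_stats.get("group_bcva_central") or {}).get(g)
            checks.append((f"group {g} BCVA central value",
                           stats.bcva_mean, central, 3))
            onset = (published_stats.get("group_onset_central") or {}).get(g)
            checks.append((f"group {g} onset central value",
                           stats.onset_mean, onset, 1))
        for label, computed, printed, decimals in checks:
            if printed is None or computed is None:
                continue
            if round_half_up(computed, decimals) != round_half_up(printed, decimals):
                notes.append(
                    f"{label}: recomputed {round_half_up(computed, decimals)} "
                    f"!= printed {printed}")
        n_total = published_stats.get("n_variants_total")
        if n_total is not None and s.n_distinct_variants != n_total:
            notes.append(
                f"distinct variant total: recomputed {s.n_distinct_variants} "
                f"!= printed {n_total}")
        n_mis = published_stats.get("n_missense")
        computed_mis = s.spectrum.get(Consequence.MISSENSE.value, 0)
        if n_mis is not None and computed_mis != n_mis:
            notes.append(
                f"distinct missense count: recomputed {computed_mis} "
                f"!= printed {n_mis}")
    return notes


def load_published_stats() -> dict:
    """The source table's printed headline statistics (validation only)."""
    return json.loads(fixture_path("table1_published_stats.json")
                      .read_text(encoding="utf-8"))
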