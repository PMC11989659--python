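"""Pipeline configuration: the handful of thresholds that matter.

All thresholds have clinical meaning and sensible defaults; they are
exposed so sensitivity to any one of them can be probed without editing
code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .phenotype import LOW_VISION_CODES

__all__ = ["PipelineConfig", "SEVERITY_FROM_TABLE", "SEVERITY_COMPUTED"]

#: severity-stratified statistics use the table's printed severity labels
SEVERITY_FROM_TABLE = "table_labels"
#: severity-stratified statistics use classify_severity on each record
SEVERITY_COMPUTED = "computed"


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the cohort pipeline.

    delta_threshold
        SpliceAI delta score at or above which a splice gain/loss is
        called (fraction in (0, 1)).
    near_splice_window
        Nucleotide distance from the exon boundary within which an
        intronic variant counts as near-splice (functional-site region);
        beyond it the variant is deep intronic.
    adult_onset_threshold
        Age (years) splitting childhood/adolescent onset from adult
        onset when stratifying onset statistics.
    late_onset_threshold
        Age (years) at or above which onset counts as the late-onset
        disease subtype.
    low_vision_codes
        Mapping of off-chart acuity notations to logMAR values.
    severity_source
        Where severity-stratified statistics take each patient's class
        from: the cohort table's printed labels, or the five-criteria
        classifier applied to the record's own fields.
    report_decimals
        Decimal places used for the rounded report columns (ages /
        percentages, and logMAR means); raw full-precision values are
        always retained alongside.
    """

    delta_threshold: float = 0.2
    near_splice_window: int = 20
    adult_onset_threshold: float = 18.0
    late_onset_threshold: float = 45.0
    low_vision_codes: Mapping[str, float] = field(
        default_factory=lambda: dict(LOW_VISION_CODES))
    severity_source: str = SEVERITY_FROM_TABLE
    age_decimals: int = 1
    logmar_decimals: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.delta_threshold < 1.0):
            raise ValueError("delta_threshold must be in (0, 1)")
        if self.near_splice_window < 3:
            raise ValueError("near_splice_window must be >= 3")
        if self.adult_onset_threshold <= 0 or self.late_onset_threshold <= 0:
            raise ValueError("onset thresholds must be positive")
        for code, value in self.low_vision_codes.items():
            if not (0.0 <= value <= 2.28):
                raise ValueError(
                    f"low-vision code {code!r} maps outside [0, 2.28]: {value}")
        if self.severity_source not in (SEVERITY_FROM_TABLE, SEVERITY_COMPUTED):
            raise ValueError(
                f"unknown severity_source {self.severity_source!r}")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
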