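"""Patient-level record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .grouping import Zygosity
from .hgvs import VariantDescriptor
from .phenotype import VisualAcuity

__all__ = ["PatientRecord"]


@dataclass
class PatientRecord:
    """Demographics, acuities, imaging labels and the patient's alleles.

    ``af_type``/``fundus_type``/``erg_type`` are 1-3 labels or None when
    the examination was not available.  ``severity_label`` carries a
    pre-assigned severity class (1-3) when the cohort table provides one;
    ``evaluable`` marks whether the patient enters severity-stratified
    statistics.  ``alleles`` pairs each variant with its zygosity.
    """

    id: str
    sex: str
    onset_age: float
    exam_age: float
    acuity_od: VisualAcuity
    acuity_os: VisualAcuity
    af_type: Optional[int] = None
    fundus_type: Optional[int] = None
    erg_type: Optional[int] = None
    severity_label: Optional[int] = None
    evaluable: bool = True
    alleles: List[Tuple[VariantDescriptor, Zygosity]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"patient {self.id}: sex must be M or F, got {self.sex!r}")
        if not (0 <= self.onset_age <= self.exam_age):
            raise ValueError(
                f"patient {self.id}: requires 0 <= onset_age <= exam_age "
                f"(got onset {self.onset_age}, exam {self.exam_age})"
            )
        for name, label in (("af_type", self.af_type),
                            ("fundus_type", self.fundus_type),
                            ("erg_type", self.erg_type)):
            if label is not None and label not in (1, 2, 3):
                raise ValueError(
                    f"patient {self.id}: {name} must be 1-3 or absent, got {label}"
                )

    @property
    def n_alleles(self) -> int:
        return sum(z.allele_count for _, z in self.alleles)

    @property
    def is_homozygous(self) -> bool:
        return len(self.alleles) == 1 and self.alleles[0][1] is Zygosity.HOM
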