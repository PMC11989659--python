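"""Visual-acuity conversion and phenotype-severity classification.

Best-corrected visual acuity (BCVA) is held on the logMAR scale (higher
is worse).  Off-chart low-vision notations are mapped to fixed logMAR
values: counting fingers (CF, also written "FC/<distance>") to 1.98 and
hand motion (HM) to 2.28.

Phenotype severity is scored from five clinical criteria — age of onset,
BCVA in the better eye, fundus appearance type, autofluorescence (AF)
type and ERG type:

======== ===================== =================== ====== ==== =====
class    onset (years)         better-eye logMAR   fundus AF   ERG
======== ===================== =================== ====== ==== =====
mild     later onset (> 15)    < 0.78              1      1    1
severe   early onset (< 10)    > 1.0               3      3    3
======== ===================== =================== ====== ==== =====

A patient meeting at least two mild criteria (and fewer than two severe)
is mild; at least two severe criteria (and fewer than two mild) is
severe; anyone else is moderate.  All inequalities are strict: onset of
exactly 10 or 15 years, or a better-eye logMAR of exactly 0.78 or 1.0,
matches neither side.  Missing type labels simply contribute no hit.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Mapping, Optional

__all__ = [
    "VisualAcuity",
    "SeverityClass",
    "SeverityAssignment",
    "AcuityParseError",
    "to_logmar",
    "better_eye",
    "classify_severity",
    "LOW_VISION_CODES",
    "LOGMAR_CF",
    "LOGMAR_HM",
]

logger = logging.getLogger(__name__)

LOGMAR_CF = 1.98
LOGMAR_HM = 2.28

#: Default mapping of off-chart low-vision notations to logMAR values.
LOW_VISION_CODES: Mapping[str, float] = {"CF": LOGMAR_CF, "FC": LOGMAR_CF,
                                         "HM": LOGMAR_HM}

_LOGMAR_MIN, _LOGMAR_MAX = -0.3, LOGMAR_HM


class AcuityParseError(ValueError):
    """Raised for unrecognized acuity notation (never a silent default)."""


def to_logmar(raw: str, codes: Mapping[str, float] = LOW_VISION_CODES) -> float:
    """Convert an acuity notation string to logMAR.

    Decimal strings pass through unchanged; "CF", "HM" and
    distance-qualified forms such as "FC/40cm" map to their fixed values.
    """
    text = str(raw).strip()
    if not text:
        raise AcuityParseError("empty acuity notation")
    code = text.split("/", 1)[0].upper()
    if code in codes:
        return float(codes[code])
    try:
        value = float(text)
    except ValueError:
        raise AcuityParseError(f"unrecognized acuity notation: {raw!r}") from None
    if not (_LOGMAR_MIN <= value <= _LOGMAR_MAX):
        raise AcuityParseError(
            f"logMAR value {value} outside plausible range "
            f"[{_LOGMAR_MIN}, {_LOGMAR_MAX}]"
        )
    return value


@dataclass(frozen=True)
class VisualAcuity:
    """One eye's acuity: the raw notation and its logMAR value."""

    raw: str
    logmar: float

    @classmethod
    def parse(cls, raw: str,
              codes: Mapping[str, float] = LOW_VISION_CODES) -> "VisualAcuity":
        return cls(raw=str(raw).strip(), logmar=to_logmar(raw, codes))


def better_eye(od: Optional[float], os: Optional[float]) -> float:
    """BCVA of the better eye: the minimum logMAR (lower = better vision).

    When one eye is absent the present eye is returned with a logged
    note; both absent is an error.
    """
    if od is None and os is None:
        raise ValueError("better_eye requires at least one eye's acuity")
    if od is None or os is None:
        logger.info("better_eye: only one eye available; using it")
        return od if os is None else os
    return min(od, os)


class SeverityClass(enum.IntEnum):
    MILD = 1
    MODERATE = 2
    SEVERE = 3


@dataclass(frozen=True)
class SeverityAssignment:
    klass: Optional[SeverityClass]
    mild_hits: int
    severe_hits: int
    fields_available: int
    conflict: bool = False

    @property
    def unclassifiable(self) -> bool:
        return self.klass is None


def classify_severity(
    onset: Optional[float],
    better: Optional[float],
    fundus: Optional[int] = None,
    af: Optional[int] = None,
    erg: Optional[int] = None,
) -> SeverityAssignment:
    """Score the five severity criteria and assign a class.

    ``onset`` is age of onset in years, ``better`` the better-eye
    logMAR; ``fundus``, ``af`` and ``erg`` are type labels 1-3 or None.
    Missing onset or acuity makes the patient unclassifiable.  The
    degenerate case of two or more hits on both sides resolves to
    moderate with ``conflict=True`` (never observed clinically).
    """
    if onset is None or better is None:
        return SeverityAssignment(klass=None, mild_hits=0, severe_hits=0,
                                  fields_available=0)
    labels = [lab for lab in (fundus, af, erg) if lab is not None]
    if any(lab not in (1, 2, 3) for lab in labels):
        raise ValueError(f"type labels must be 1, 2 or 3; got {labels}")
    fields_available = 2 + len(labels)

    mild_hits = sum((
        onset > 15,
        better < 0.78,
        fundus == 1,
        af == 1,
        erg == 1,
    ))
    severe_hits = sum((
        onset < 10,
        better > 1.0,
        fundus == 3,
        af == 3,
        erg == 3,
    ))

    conflict = mild_hits >= 2 and severe_hits >= 2
    if conflict:
        logger.warning(
            "severity conflict: %d mild and %d severe hits; "
            "resolving to moderate", mild_hits, severe_hits)
        klass = SeverityClass.MODERATE
    elif mild_hits >= 2:
        klass = SeverityClass.MILD
    elif severe_hits >= 2:
        klass = SeverityClass.SEVERE
    else:
        klass = SeverityClass.MODERATE
    return SeverityAssignment(klass=klass, mild_hits=mild_hits,
                              severe_hits=severe_hits,
                              fields_available=fields_available,
                              conflict=conflict)
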