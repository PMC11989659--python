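"""Parsing of HGVS-style variant notation into structured descriptors.

Handles the subset of HGVS nomenclature that appears in clinical
ABCA4/Stargardt variant tables: coding-DNA (``c.``) substitutions,
deletions, duplications, insertions and delins — including intronic
positions written as exon-anchor plus signed offset (``c.1937+392G>A``) —
protein (``p.``) missense, nonsense and frameshift descriptions, and
genomic copy-number deletions written as ``chr1:94480267-94482198del``.

Coordinates are taken at face value: cDNA positions are 1-based
coding-sequence positions, genomic regions 1-based inclusive, and no
genome-to-transcript projection or reference-sequence validation is
performed.  Unsupported constructs raise :class:`HgvsParseError` — there
is no best-effort guessing, because downstream allele classification
changes genotype-group assignments.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "EditKind",
    "Consequence",
    "CdnaChange",
    "ProteinChange",
    "GenomicRegion",
    "VariantDescriptor",
    "HgvsParseError",
    "parse_cdna",
    "parse_protein",
    "parse_genomic_region",
    "parse_variant",
    "infer_consequence",
    "DEFAULT_NEAR_SPLICE_WINDOW",
]

#: Intronic variants within this many nucleotides of an exon boundary are
#: "near-splice" (their effect is prediction-dependent); farther ones are
#: deep intronic.  Chosen so that -3/+5 offsets are near-splice while
#: +392/+782 offsets are deep intronic.
DEFAULT_NEAR_SPLICE_WINDOW = 20

# characters occasionally pasted from typeset tables
_DASH_NORMALIZE = str.maketrans({"−": "-", "–": "-", "—": "-"})

_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr "
    "Trp Tyr Val Ter".split()
)


class HgvsParseError(ValueError):
    """Raised for malformed or unsupported HGVS notation."""


class EditKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    CANONICAL_SPLICE = "canonical_splice"
    NEAR_SPLICE_INTRONIC = "near_splice_intronic"
    DEEP_INTRONIC = "deep_intronic"
    CNV_DELETION = "cnv_deletion"
    START_LOSS = "start_loss"
    OTHER = "other"


def _normalize(text: str) -> str:
    return text.translate(_DASH_NORMALIZE).strip().replace(" ", "")


@dataclass(frozen=True)
class CdnaChange:
    """A coding-DNA level change at a single anchor position.

    ``anchor_position`` is the 1-based coding-sequence coordinate;
    ``intron_offset`` is 0 for exonic positions and the signed nucleotide
    offset into the intron otherwise (``c.6006-3C>A`` has anchor 6006,
    offset -3).  ``end_position`` is set for ranged edits
    (``c.100_102del``) and equals ``anchor_position`` otherwise.
    """

    anchor_position: int
    intron_offset: int
    edit_kind: EditKind
    ref_allele: str = ""
    alt_allele: str = ""
    end_position: Optional[int] = None
    end_intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.anchor_position < 1:
            raise HgvsParseError(
                f"cDNA anchor position must be >= 1, got {self.anchor_position}"
            )
        if self.edit_kind is EditKind.SUBSTITUTION:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise HgvsParseError(
                    "substitution requires single-base ref and alt alleles"
                )

    @property
    def is_intronic(self) -> bool:
        return self.intron_offset != 0

    @property
    def span_length(self) -> Optional[int]:
        """Length in nt of the affected reference span, when exonic."""
        if self.is_intronic:
            return None
        end = self.end_position if self.end_position is not None else self.anchor_position
        return end - self.anchor_position + 1

    def format(self) -> str:
        """Render back to a normalized ``c.`` string."""
        pos = f"{self.anchor_position}"
        if self.intron_offset:
            pos += f"{self.intron_offset:+d}"
        if self.end_position is not None and (
            self.end_position != self.anchor_position
            or self.end_intron_offset != self.intron_offset
        ):
            pos += f"_{self.end_position}"
            if self.end_intron_offset:
                pos += f"{self.end_intron_offset:+d}"
        if self.edit_kind is EditKind.SUBSTITUTION:
            return f"c.{pos}{self.ref_allele}>{self.alt_allele}"
        if self.edit_kind is EditKind.DELETION:
            return f"c.{pos}del"
        if self.edit_kind is EditKind.DUPLICATION:
            return f"c.{pos}dup"
        if self.edit_kind is EditKind.INSERTION:
            return f"c.{pos}ins{self.alt_allele}"
        return f"c.{pos}delins{self.alt_allele}"


@dataclass(frozen=True)
class ProteinChange:
    """A protein-level change: ``p.Gln1852ArgfsTer3`` -> Gln/1852/Arg, fs, 3."""

    ref_residue: str
    residue_number: int
    alt_residue: str
    frameshift: bool = False
    fs_ter_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise HgvsParseError(
                f"protein residue number must be >= 1, got {self.residue_number}"
            )

    def format(self) -> str:
        s = f"p.{self.ref_residue}{self.residue_number}{self.alt_residue}"
        if self.frameshift:
            s += "fs"
            if self.fs_ter_distance is not None:
                s += f"Ter{self.fs_ter_distance}"
        return s


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval deletion, 1-based inclusive."""

    chromosome: str
    start: int
    end: int
    operation: str = "deletion"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise HgvsParseError(
                f"genomic region start {self.start} > end {self.end}"
            )

    def format(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}del"


_POS_RE = r"(?P<{p}anchor>\d+)(?P<{p}offset>[+-]\d+)?"
_CDNA_RE = re.compile(
    r"^c\."
    + _POS_RE.format(p="")
    + r"(?:_" + _POS_RE.format(p="end_") + r")?"
    + r"(?P<edit>"
    r"(?P<ref>[ACGTN]+)>(?P<alt>[ACGTN]+)"
    r"|delins(?P<delins_seq>[ACGTN]+)"
    r"|del(?P<del_seq>[ACGTN]+)?"
    r"|dup(?P<dup_seq>[ACGTN]+)?"
    r"|ins(?P<ins_seq>[ACGTN]+)"
    r")$"
)

_PROTEIN_RE = re.compile(
    r"^p\.\(?"
    r"(?P<ref>[A-Z][a-z]{2})(?P<num>\d+)"
    r"(?P<alt>[A-Z][a-z]{2}|Ter|\*|\?)"
    r"(?P<fs>fs(?:Ter(?P<fsnum>\d+|\?))?)?"
    r"\)?$"
)

_GENOMIC_RE = re.compile(
    r"^(?:chr)?(?P<chrom>[0-9XYM]+):(?P<start>\d+)[-_](?P<end>\d+)del$"
)


def parse_cdna(text: str) -> CdnaChange:
    """Parse a coding-DNA HGVS string such as ``c.6006-3C>A``.

    Raises
    ------
    HgvsParseError
        If the string is malformed or uses an unsupported construct.
    """
    raw = _normalize(text)
    if not raw.startswith("c."):
        raise HgvsParseError(f"cDNA notation must begin with 'c.': {text!r}")
    m = _CDNA_RE.match(raw)
    if m is None:
        raise HgvsParseError(f"unsupported or malformed cDNA notation: {text!r}")
    anchor = int(m.group("anchor"))
    offset = int(m.group("offset") or 0)
    end_pos = m.group("end_anchor")
    end = int(end_pos) if end_pos else None
    end_off = int(m.group("end_offset") or 0) if end_pos else offset

    if m.group("ref"):
        if end is not None:
            raise HgvsParseError(
                f"ranged substitutions are not supported: {text!r}"
            )
        return CdnaChange(anchor, offset, EditKind.SUBSTITUTION,
                          m.group("ref"), m.group("alt"))
    if m.group("delins_seq"):
        return CdnaChange(anchor, offset, EditKind.DELINS,
                          alt_allele=m.group("delins_seq"),
                          end_position=end, end_intron_offset=end_off)
    edit = m.group("edit")
    if edit.startswith("delins"):
        return CdnaChange(anchor, offset, EditKind.DELINS,
                          end_position=end, end_intron_offset=end_off)
    if edit.startswith("del"):
        return CdnaChange(anchor, offset, EditKind.DELETION,
                          ref_allele=m.group("del_seq") or "",
                          end_position=end, end_intron_offset=end_off)
    if edit.startswith("dup"):
        return CdnaChange(anchor, offset, EditKind.DUPLICATION,
                          ref_allele=m.group("dup_seq") or "",
                          end_position=end, end_intron_offset=end_off)
    if edit.startswith("ins"):
        if end is None:
            raise HgvsParseError(
                f"insertion requires a position range: {text!r}"
            )
        return CdnaChange(anchor, offset, EditKind.INSERTION,
                          alt_allele=m.group("ins_seq"),
                          end_position=end, end_intron_offset=end_off)
    raise HgvsParseError(f"unsupported edit kind in {text!r}")  # pragma: no cover


def parse_protein(text: str) -> ProteinChange:
    """Parse a protein HGVS string such as ``p.Gln1852ArgfsTer3``."""
    raw = _normalize(text)
    if not raw.startswith("p."):
        raise HgvsParseError(f"protein notation must begin with 'p.': {text!r}")
    m = _PROTEIN_RE.match(raw)
    if m is None:
        raise HgvsParseError(f"unsupported or malformed protein notation: {text!r}")
    ref = m.group("ref")
    alt = m.group("alt")
    if alt == "*":
        alt = "Ter"
    if ref not in _AA3:
        raise HgvsParseError(f"unknown amino-acid code {ref!r} in {text!r}")
    if alt not in _AA3 and alt != "?":
        raise HgvsParseError(f"unknown amino-acid code {alt!r} in {text!r}")
    fs = m.group("fs") is not None
    fsnum = m.group("fsnum")
    ter_distance = int(fsnum) if fsnum and fsnum != "?" else None
    return ProteinChange(ref, int(m.group("num")), alt,
                         frameshift=fs, fs_ter_distance=ter_distance)


def parse_genomic_region(text: str) -> GenomicRegion:
    """Parse a genomic deletion such as ``chr1:94480267-94482198del``."""
    raw = _normalize(text)
    m = _GENOMIC_RE.match(raw)
    if m is None:
        raise HgvsParseError(f"unsupported genomic region notation: {text!r}")
    return GenomicRegion("chr" + m.group("chrom"),
                         int(m.group("start")), int(m.group("end")))


@dataclass(frozen=True)
class VariantDescriptor:
    """One sequence change, with its inferred consequence class.

    At least one of ``cdna``/``genomic`` must be present.  ``key`` is the
    normalized cDNA string (genomic string for CNVs) used to deduplicate
    variants across patients and to join splice-score tables.
    """

    cdna: Optional[CdnaChange] = None
    protein: Optional[ProteinChange] = None
    genomic: Optional[GenomicRegion] = None
    novel: bool = False
    consequence: Consequence = field(default=Consequence.OTHER)

    def __post_init__(self) -> None:
        if self.cdna is None and self.genomic is None:
            raise HgvsParseError(
                "variant requires at least a cDNA or genomic description"
            )

    @property
    def key(self) -> str:
        if self.cdna is not None:
            return self.cdna.format()
        assert self.genomic is not None
        return self.genomic.format()

    def format(self) -> str:
        parts = []
        if self.cdna is not None:
            parts.append(self.cdna.format())
        if self.protein is not None:
            parts.append(f"({self.protein.format()})")
        if self.genomic is not None:
            parts.append(self.genomic.format())
        return "".join(parts)


def infer_consequence(
    cdna: Optional[CdnaChange] = None,
    protein: Optional[ProteinChange] = None,
    genomic: Optional[GenomicRegion] = None,
    near_splice_window: int = DEFAULT_NEAR_SPLICE_WINDOW,
) -> Consequence:
    """Infer the consequence class of a variant.

    Protein notation dominates when present: a frameshift token means
    frameshift, an alternate residue of Ter without frameshift means
    nonsense, a change at residue 1 of the initiator Met means start loss,
    and two distinct ordinary residues mean missense.  Without protein
    notation the cDNA intron offset decides: |offset| in {1, 2} is a
    canonical splice-site change, |offset| up to ``near_splice_window`` is
    near-splice intronic (prediction-dependent), and beyond that deep
    intronic.  Exonic indels without protein annotation are classified by
    span length modulo 3.  A genomic deletion is a copy-number deletion.
    """
    if near_splice_window < 3:
        raise ValueError("near_splice_window must be >= 3")
    if genomic is not None and cdna is None:
        if genomic.operation == "deletion":
            return Consequence.CNV_DELETION
        raise HgvsParseError(  # pragma: no cover - only deletions modelled
            f"unsupported genomic operation {genomic.operation!r}"
        )
    if protein is not None:
        p = protein
        if p.frameshift:
            return Consequence.FRAMESHIFT
        if p.residue_number == 1 and p.ref_residue == "Met" and p.alt_residue != "Met":
            return Consequence.START_LOSS
        if p.alt_residue == "Ter":
            return Consequence.NONSENSE
        if p.ref_residue == p.alt_residue or p.alt_residue == "?":
            return Consequence.OTHER
        return Consequence.MISSENSE
    if cdna is None:
        raise HgvsParseError("unclassifiable: no usable cDNA, protein or genomic field")
    if cdna.is_intronic:
        off = abs(cdna.intron_offset)
        if off <= 2:
            return Consequence.CANONICAL_SPLICE
        if off <= near_splice_window:
            return Consequence.NEAR_SPLICE_INTRONIC
        return Consequence.DEEP_INTRONIC
    if cdna.edit_kind is EditKind.SUBSTITUTION:
        # exonic substitution with no protein annotation: effect unknown
        return Consequence.OTHER
    if cdna.edit_kind in (EditKind.DELETION, EditKind.DUPLICATION):
        length = cdna.span_length
        if length is None:
            return Consequence.OTHER
        return Consequence.INFRAME_INDEL if length % 3 == 0 else Consequence.FRAMESHIFT
    if cdna.edit_kind is EditKind.INSERTION:
        return (Consequence.INFRAME_INDEL if len(cdna.alt_allele) % 3 == 0
                else Consequence.FRAMESHIFT)
    return Consequence.OTHER


def parse_variant(
    cdna_hgvs: str = "",
    protein_hgvs: str = "",
    genomic_region: str = "",
    novel: bool = False,
    near_splice_window: int = DEFAULT_NEAR_SPLICE_WINDOW,
) -> VariantDescriptor:
    """Build a :class:`VariantDescriptor` from table fields (empty = absent)."""
    cdna = parse_cdna(cdna_hgvs) if cdna_hgvs.strip() else None
    protein = parse_protein(protein_hgvs) if protein_hgvs.strip() else None
    genomic = parse_genomic_region(genomic_region) if genomic_region.strip() else None
    consequence = infer_consequence(cdna, protein, genomic, near_splice_window)
    return VariantDescriptor(cdna=cdna, protein=protein, genomic=genomic,
                             novel=novel, consequence=consequence)
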