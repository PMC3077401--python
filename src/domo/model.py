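"""Shared domain types for the S-gene domain-movement pipeline.

The objects here mirror the anatomy of a Type I / Type IIG
restriction-modification specificity (S) gene: an allele is a nucleotide
sequence organised as

    flank - x - TRD1 - y - central - x - [z -] TRD2 [- z] - y - flank

where ``x``/``y`` (and optionally ``z``) are short direct-repeat classes that
flank the target recognition domains (TRDs) and the central region is a
tandem repeat whose copy number sets the spacer of the bipartite recognition
site. All coordinates are 0-based half-open; 1-based inclusive coordinates
appear only at the GFF3 boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

DNA_ALPHABET = frozenset("ACGT")
IUPAC_EXTRA = frozenset("RYSWKMBDHVN")

#: Event classes inferred by the pipeline (and injected by the simulator).
EVENT_TYPES = (
    "SUBSTITUTION",
    "MOVEMENT",
    "DELETION",
    "DUPLICATION",
    "CENTRAL_COPY_CHANGE",
    "INTER_LOCUS_SHARING",
)

REPEAT_CLASSES = ("X", "Y", "Z")


class DomoError(Exception):
    """Base class for package errors."""


class NoArchitectureError(DomoError):
    """Raised when repeat copies interleave in no recognized cassette pattern.

    Carries the offending pair/copy list so callers can fall back to the
    dotplot screen.
    """

    def __init__(self, message: str, pairs=None):
        super().__init__(message)
        self.pairs = list(pairs) if pairs is not None else []


@dataclass(frozen=True)
class SGeneRecord:
    """One S-gene allele: a nucleotide sequence with strain/locus identity."""

    seq_id: str
    strain: str
    locus_id: str
    sequence: str
    degenerate: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.seq_id!r}")
        allowed = DNA_ALPHABET | (IUPAC_EXTRA if self.degenerate else frozenset())
        for offset, base in enumerate(self.sequence):
            if base not in allowed:
                raise ValueError(
                    f"record {self.seq_id!r}: non-{'IUPAC' if self.degenerate else 'ACGT'}"
                    f" character {base!r} at offset {offset}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatClass:
    name: str  # "X", "Y" or "Z"
    expected_length_bp: Optional[int] = None

    def __post_init__(self):
        if self.name not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.name!r}")
        if self.expected_length_bp is not None and self.expected_length_bp <= 0:
            raise ValueError("expected_length_bp must be positive")


@dataclass
class RepeatPair:
    """Two same-orientation near-identical copies of a repeat within a gene."""

    left: tuple[int, int]  # [start, end)
    right: tuple[int, int]
    length_bp: int
    identity: float
    class_name: Optional[str] = None  # "X"/"Y"/"Z" once classified

    def __post_init__(self):
        ls, le = self.left
        rs, re = self.right
        if le - ls != self.length_bp or re - rs != self.length_bp:
            raise ValueError("interval lengths disagree with length_bp")
        if le > rs:
            raise ValueError("left copy must end before right copy starts")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity out of [0,1]")

    @property
    def copies(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.left, self.right)

    def contains(self, other: "RepeatPair") -> bool:
        """True if both of ``other``'s copies lie within this pair's copies."""
        return (
            self.left[0] <= other.left[0]
            and other.left[1] <= self.left[1]
            and self.right[0] <= other.right[0]
            and other.right[1] <= self.right[1]
        )


@dataclass
class RepeatCopy:
    """A single located occurrence of a classified repeat."""

    class_name: str
    start: int
    end: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TandemRepeat:
    """A tandem run: ``copy_number`` complete units of ``unit_sequence``."""

    start: int
    end: int
    unit_sequence: str
    copy_number: int

    def __post_init__(self):
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        span = self.end - self.start
        unit = self.unit_length_bp
        if unit and not (unit * self.copy_number <= span < unit * (self.copy_number + 1)):
            raise ValueError("interval length inconsistent with unit x copies")

    @property
    def unit_length_bp(self) -> int:
        return len(self.unit_sequence)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GeneArchitecture:
    """Ordered segmentation of one allele into flanks, TRD slots and central."""

    seq_id: str
    trd_slots: list[tuple[int, int]]
    central_interval: Optional[tuple[int, int]] = None
    central: Optional[TandemRepeat] = None
    repeat_pairs: list[RepeatPair] = field(default_factory=list)
    repeat_copies: list[RepeatCopy] = field(default_factory=list)

    def __post_init__(self):
        if not 1 <= len(self.trd_slots) <= 3:
            raise ValueError("an architecture carries 1-3 TRD slots")
        prev_end = -1
        for s, e in self.trd_slots:
            if s >= e:
                raise ValueError("empty TRD slot")
            if s < prev_end:
                raise ValueError("TRD slots must be ordered and disjoint")
            prev_end = e

    @property
    def n_trds(self) -> int:
        return len(self.trd_slots)


@dataclass(frozen=True)
class TRDInstance:
    """One TRD occurrence: an allele's slot sequence with its position index."""

    seq_id: str
    position_index: int  # 1-based slot
    start: int
    end: int
    sequence: str
    strain: str = "NA"
    locus_id: str = "NA"

    def __post_init__(self):
        if self.end - self.start != len(self.sequence):
            raise ValueError("instance sequence length disagrees with interval")

    @property
    def key(self) -> tuple[str, int]:
        return (self.seq_id, self.position_index)


@dataclass
class DomainCluster:
    """A homology group of TRD instances sharing one label ('a', 'b', ...)."""

    label: str
    members: list[TRDInstance]
    representative: str

    def keys(self) -> set[tuple[str, int]]:
        return {m.key for m in self.members}


@dataclass
class EventCall:
    """An inferred recombination event class with its supporting evidence."""

    type: str
    locus_id: str
    evidence: list[tuple[str, int, str]]  # (seq_id, position_index, label)
    confidence_note: str = ""

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.type == "MOVEMENT":
            positions = {pos for _, pos, _ in self.evidence}
            if len(positions) < 2:
                raise ValueError("MOVEMENT evidence must span two position indices")


def domain_label(index: int) -> str:
    """0 -> 'a', 1 -> 'b', ..., 25 -> 'z', 26 -> 'aa', ... (spreadsheet style)."""
    if index < 0:
        raise ValueError("label index must be >= 0")
    chars = []
    index += 1
    while index:
        index, rem = divmod(index - 1, 26)
        chars.append(chr(ord("a") + rem))
    return "".join(reversed(chars))


def check_unique_strain_locus(records: Iterable[SGeneRecord]) -> None:
    """Enforce uniqueness of (strain, locus) pairs within a dataset."""
    seen: dict[tuple[str, str], str] = {}
    for rec in records:
        key = (rec.strain, rec.locus_id)
        if key == ("NA", "NA"):
            continue
        if key in seen:
            raise ValueError(
                f"duplicate (strain, locus) pair {key} for records "
                f"{seen[key]!r} and {rec.seq_id!r}"
            )
        seen[key] = rec.seq_id
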