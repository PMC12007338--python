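"""Core in-memory containers shared by every stage of the polisher.

All coordinates are 0-based internally; the mpileup text format and the
error-list TSV use 1-based positions, converted at the I/O boundary.
Error types are always defined from the draft assembly's perspective:

* ``substitution`` -- the draft carries the wrong nucleotide.
* ``insertion`` -- the draft carries spurious bases (aligned sources show a
  deletion relative to the draft); correction removes them.
* ``deletion`` -- the draft is missing bases (aligned sources show an
  insertion relative to the draft); correction inserts them after the
  anchor position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"
ERROR_TYPES = (SUBSTITUTION, INSERTION, DELETION)

# Lifecycle tags for a candidate error.
ST_DETECTED = "detected"
ST_CONFIRMED = "confirmed"
ST_ADJUSTED = "adjusted"
ST_SPLIT = "split"
ST_RETAINED = "retained_unsupported"
ST_REMOVED = "removed"
STATUSES = (ST_DETECTED, ST_CONFIRMED, ST_ADJUSTED, ST_SPLIT, ST_RETAINED, ST_REMOVED)

#: statuses whose edits are applied by the corrector
APPLICABLE_STATUSES = frozenset(STATUSES) - {ST_REMOVED}


@dataclass(frozen=True, slots=True)
class Observation:
    """How one aligned source (reference block or read) relates to the draft
    at a single column.

    ``kind`` is ``match``, ``mismatch`` (with ``base`` set) or ``gap`` (this
    column lies inside a previously declared deletion on this source).
    ``insertion`` holds extra source bases that follow this column
    (source has sequence the draft lacks); ``deletion`` holds the draft bases
    starting at the next column that the source lacks.  Indels are anchored
    on the draft base immediately preceding the event, the mpileup
    convention.
    """

    source: int
    kind: str = "match"
    base: str = ""
    insertion: str = ""
    deletion: str = ""


@dataclass(slots=True)
class PileupColumn:
    contig: str
    pos: int  # 0-based draft coordinate
    draft_base: str
    observations: list[Observation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        """Number of sources covering this column (gap placeholders count)."""
        return len(self.observations)


@dataclass(slots=True)
class Pileup:
    """All-positions pileup: one column per draft base for every contig."""

    contigs: dict[str, list[PileupColumn]] = field(default_factory=dict)
    #: 0-based start coordinate of every source segment, indexed by source id
    source_starts: list[int] = field(default_factory=list)

    def validate_against(self, draft: dict[str, str]) -> None:
        for name, seq in draft.items():
            cols = self.contigs.get(name)
            if cols is None:
                raise ValueError(f"pileup lacks contig {name!r}")
            if len(cols) != len(seq):
                raise ValueError(
                    f"pileup for contig {name!r} has {len(cols)} columns, "
                    f"draft has {len(seq)} bases"
                )


@dataclass(frozen=True, slots=True)
class AlignmentBlock:
    """One local alignment of a reference genome against the draft."""

    query_id: str
    contig: str
    start: int  # 0-based, half-open
    end: int
    identity: float  # fraction in [0, 1]

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"alignment block {self.query_id}: end ({self.end}) must be "
                f"> start ({self.start})"
            )


@dataclass(frozen=True, slots=True)
class HomopolymerContext:
    """Maximal run of one nucleotide in the draft containing a position."""

    base: str
    start: int  # 0-based
    end: int  # exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class CandidateError:
    """One putative assembly error with its full evidence trail.

    ``position`` semantics by type (0-based):
      substitution -- the erroneous draft base;
      insertion    -- the first spurious draft base (``draft_seq`` holds the
                      spurious bases, ``correction_seq`` is empty);
      deletion     -- the draft base after which bases are missing
                      (``draft_seq`` empty, ``correction_seq`` holds the
                      missing bases; an anchor of -1 prepends to the contig).
    """

    contig: str
    position: int
    error_type: str
    length: int
    draft_seq: str
    correction_seq: str
    reference_adp: float = 0.0
    regional_adp: float = 0.0
    score: float = 0.0
    read_adp: float | None = None
    status: str = ST_DETECTED
    pass_found: int = 0
    original_position: int | None = None

    def __post_init__(self) -> None:
        if self.error_type not in ERROR_TYPES:
            raise ValueError(f"unknown error type {self.error_type!r}")
        if self.error_type == SUBSTITUTION:
            if not (self.draft_seq and self.correction_seq):
                raise ValueError("substitution needs draft and correction bases")
        elif self.error_type == INSERTION:
            if not self.draft_seq or self.correction_seq:
                raise ValueError("insertion error carries draft bases only")
        elif not self.correction_seq or self.draft_seq:
            raise ValueError("deletion error carries correction bases only")
        if self.draft_seq == self.correction_seq:
            raise ValueError("correction must differ from draft sequence")

    @property
    def applicable(self) -> bool:
        return self.status in APPLICABLE_STATUSES

    def moved_to(self, position: int, **changes) -> "CandidateError":
        orig = self.original_position if self.original_position is not None else self.position
        return replace(self, position=position, original_position=orig, **changes)


def sort_errors(errors: list[CandidateError]) -> list[CandidateError]:
    """Deterministic ordering used everywhere an error list is emitted."""
    return sorted(errors, key=lambda e: (e.contig, e.position, e.error_type, e.length))
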