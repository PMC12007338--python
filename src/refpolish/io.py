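"""Reading and writing the formats the polisher touches.

FASTA handling goes through Biopython.  The pileup contract is the SAMtools
mpileup *text* dialect in its all-positions variant (every draft position has
a line, zero-coverage lines included), which is what upstream
``samtools mpileup -aa`` emits; there is no BAM/SAM parsing here.  Upstream
pileup generation must disable depth capping so every aligned block is
represented.  Base/mapping quality characters are consumed and ignored.
"""

from __future__ import annotations

import csv
import os

from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .model import (
    AlignmentBlock,
    CandidateError,
    ERROR_TYPES,
    Observation,
    Pileup,
    PileupColumn,
    STATUSES,
    sort_errors,
)

_IUPAC = set("ACGTUNRYSWKMBDHV")

ERROR_TABLE_COLUMNS = [
    "contig", "position", "error_type", "length", "draft_seq",
    "correction_seq", "reference_adp", "regional_adp", "score", "read_adp",
    "status", "original_position",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read nucleotide FASTA into an ordered ``{contig: sequence}`` map.

    Sequences are uppercased; contigs are keyed by the first
    whitespace-delimited header token, in file order.
    """
    assembly: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in assembly:
            raise ValueError(f"duplicate contig name {record.id!r} in {path}")
        seq = str(record.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(
                f"record {record.id!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )
        assembly[record.id] = seq
    if not assembly:
        raise ValueError(f"no FASTA records found in {path}")
    return assembly


def write_fasta(assembly: dict[str, str], path: str | os.PathLike,
                line_width: int = 80) -> None:
    """Write contigs in map order with a fixed line width (byte-reproducible)."""
    if not assembly:
        raise ValueError("refusing to write an empty assembly")
    records = (SeqRecord(Seq(seq), id=name, description="")
               for name, seq in assembly.items())
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# mpileup text

def _decode_base_string(bases: str, line_no: int) -> list[tuple[bool, str, str, str, bool]]:
    """Split one mpileup base string into per-slot tokens.

    Returns ``(starts_here, base_char, insertion, deletion_seq, ends_here)``
    per covering slot.
    """
    tokens = []
    i, n = 0, len(bases)
    while i < n:
        starts = False
        if bases[i] == "^":
            if i + 1 >= n:
                raise ValueError(f"mpileup line {line_no}: dangling '^'")
            starts = True
            i += 2  # skip the mapping-quality character
        c = bases[i]
        i += 1
        if c in ".,":
            c = "."
        elif c in "ACGTNacgtn":
            c = c.upper()
        elif c != "*":
            raise ValueError(f"mpileup line {line_no}: unexpected base char {c!r}")
        ins = dele = ""
        while i < n and bases[i] in "+-":
            sign = bases[i]
            i += 1
            j = i
            while j < n and bases[j].isdigit():
                j += 1
            if j == i:
                raise ValueError(f"mpileup line {line_no}: malformed indel length")
            length = int(bases[i:j])
            seq = bases[j:j + length].upper()
            if len(seq) != length:
                raise ValueError(f"mpileup line {line_no}: truncated indel sequence")
            i = j + length
            if sign == "+":
                ins = seq
            else:
                dele = seq
        ends = False
        if i < n and bases[i] == "$":
            ends = True
            i += 1
        tokens.append((starts, c, ins, dele, ends))
    return tokens


def parse_mpileup(path: str | os.PathLike, draft: dict[str, str]) -> Pileup:
    """Parse an all-positions mpileup file against its draft assembly.

    Source identity is positional: within a column, continuing alignment
    segments appear first (in the order established at their start) and new
    segments (``^``-marked) are appended after them, the ordering
    ``samtools`` produces for position-sorted input.  Each aligned block
    becomes one persistent source id.  Files violating slot consistency are
    rejected rather than guessed at.
    """
    pileup = Pileup()
    active: list[int] = []  # source ids of segments continuing into this column
    current_contig: str | None = None
    next_source = 0

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"mpileup line {line_no}: fewer than 4 columns")
            contig, pos_s, ref_base, depth_s = parts[:4]
            bases = parts[4] if len(parts) > 4 else "*"
            if contig not in draft:
                raise ValueError(f"mpileup line {line_no}: unknown contig {contig!r}")
            if contig != current_contig:
                if active:
                    raise ValueError(
                        f"mpileup line {line_no}: contig changed with "
                        f"{len(active)} segments still open"
                    )
                current_contig = contig
                pileup.contigs.setdefault(contig, [])
            pos = int(pos_s) - 1
            cols = pileup.contigs[contig]
            if pos != len(cols):
                raise ValueError(
                    f"mpileup line {line_no}: expected position {len(cols) + 1} "
                    f"of contig {contig!r}, got {pos + 1}"
                )
            if pos >= len(draft[contig]):
                raise ValueError(f"mpileup line {line_no}: position beyond contig end")
            draft_base = draft[contig][pos]
            ref_base = ref_base.upper()
            if ref_base not in ("*", "N") and draft_base != "N" and ref_base != draft_base:
                raise ValueError(
                    f"mpileup line {line_no}: reference base {ref_base!r} does not "
                    f"match draft base {draft_base!r} at {contig}:{pos + 1}"
                )
            depth = int(depth_s)
            column = PileupColumn(contig=contig, pos=pos, draft_base=draft_base)
            if depth == 0:
                if active:
                    raise ValueError(
                        f"mpileup line {line_no}: zero depth while {len(active)} "
                        "segments are open"
                    )
                cols.append(column)
                continue
            tokens = _decode_base_string(bases, line_no)
            if len(tokens) != depth:
                raise ValueError(
                    f"mpileup line {line_no}: decoded {len(tokens)} observations "
                    f"but depth field says {depth}"
                )
            n_cont = sum(1 for t in tokens if not t[0])
            if n_cont != len(active):
                raise ValueError(
                    f"mpileup line {line_no}: {n_cont} continuing observations "
                    f"but {len(active)} open segments"
                )
            if any(t[0] for t in tokens[:n_cont]):
                raise ValueError(
                    f"mpileup line {line_no}: segment-start observations must "
                    "follow continuing ones"
                )
            next_active: list[int] = []
            for slot, (starts, c, ins, dele, ends) in enumerate(tokens):
                if starts:
                    src = next_source
                    next_source += 1
                    pileup.source_starts.append(pos)
                else:
                    src = active[slot]
                if c == ".":
                    obs = Observation(source=src, kind="match", insertion=ins, deletion=dele)
                elif c == "*":
                    obs = Observation(source=src, kind="gap", insertion=ins, deletion=dele)
                else:
                    obs = Observation(source=src, kind="mismatch", base=c,
                                      insertion=ins, deletion=dele)
                column.observations.append(obs)
                if not ends:
                    next_active.append(src)
            active = next_active
            cols.append(column)
    if active:
        raise ValueError("mpileup ended with open segments")
    pileup.validate_against(draft)
    return pileup


def write_mpileup(pileup: Pileup, draft: dict[str, str],
                  path: str | os.PathLike) -> None:
    """Serialize a pileup back to all-positions mpileup text.

    Observations within a column are emitted sorted by segment start (then
    source id) so continuing segments precede newly started ones, matching
    the parsing contract.  Quality characters are placeholders.
    """
    starts = pileup.source_starts
    with open(path, "w") as fh:
        for contig, seq in draft.items():
            cols = pileup.contigs[contig]
            prev_sources: set[int] = set()
            for pos, col in enumerate(cols):
                if col.depth == 0:
                    fh.write(f"{contig}\t{pos + 1}\t{seq[pos]}\t0\t*\t*\n")
                    prev_sources = set()
                    continue
                nxt_sources = ({o.source for o in cols[pos + 1].observations}
                               if pos + 1 < len(cols) else set())
                obs_sorted = sorted(col.observations,
                                    key=lambda o: (starts[o.source], o.source))
                chunks = []
                for o in obs_sorted:
                    piece = ""
                    if o.source not in prev_sources:
                        piece += "^!"
                    if o.kind == "match":
                        piece += "."
                    elif o.kind == "gap":
                        piece += "*"
                    else:
                        piece += o.base
                    if o.insertion:
                        piece += f"+{len(o.insertion)}{o.insertion}"
                    if o.deletion:
                        piece += f"-{len(o.deletion)}{o.deletion}"
                    if o.source not in nxt_sources:
                        piece += "$"
                    chunks.append(piece)
                fh.write(f"{contig}\t{pos + 1}\t{seq[pos]}\t{col.depth}\t"
                         f"{''.join(chunks)}\t{'~' * col.depth}\n")
                prev_sources = {o.source for o in col.observations}


# ---------------------------------------------------------------------------
# alignment blocks

def read_alignment_blocks(path: str | os.PathLike) -> list[AlignmentBlock]:
    """Read the alignment-block table: TSV with header
    ``query_id contig start end identity length`` (0-based half-open)."""
    blocks = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            block = AlignmentBlock(
                query_id=row["query_id"], contig=row["contig"],
                start=int(row["start"]), end=int(row["end"]),
                identity=float(row["identity"]),
            )
            if "length" in row and int(row["length"]) != block.length:
                raise ValueError(
                    f"block {block.query_id}: stated length {row['length']} "
                    f"!= end - start ({block.length})"
                )
            blocks.append(block)
    return blocks


def filter_alignment_blocks(blocks: list[AlignmentBlock],
                            min_identity: float = 0.80,
                            min_length: int = 1000) -> list[AlignmentBlock]:
    """Drop poor (< 80% identity) and short (< 1000 nt) alignments; order
    preserved, boundaries inclusive."""
    return [b for b in blocks
            if b.identity >= min_identity and b.length >= min_length]


# ---------------------------------------------------------------------------
# error-list TSV

def _fmt_float(x: float | None) -> str:
    return "." if x is None else repr(float(x))


def write_error_table(errors: list[CandidateError],
                      path: str | os.PathLike) -> None:
    """Write the error list as TSV with 1-based positions, deterministically
    sorted; '.' marks empty sequences and absent values."""
    rows = sort_errors(errors)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ERROR_TABLE_COLUMNS)
        for e in rows:
            writer.writerow([
                e.contig, e.position + 1, e.error_type, e.length,
                e.draft_seq or ".", e.correction_seq or ".",
                _fmt_float(e.reference_adp), _fmt_float(e.regional_adp),
                _fmt_float(e.score), _fmt_float(e.read_adp), e.status,
                "." if e.original_position is None else e.original_position + 1,
            ])


def read_error_table(path: str | os.PathLike) -> list[CandidateError]:
    """Read an error-list TSV back into candidate errors (lossless inverse
    of :func:`write_error_table` up to the internal pass counter)."""
    errors: list[CandidateError] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ERROR_TABLE_COLUMNS:
            raise ValueError(f"unexpected error-table header in {path}: {header}")
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(ERROR_TABLE_COLUMNS):
                raise ValueError(f"{path}:{line_no}: wrong column count")
            (contig, pos_s, etype, length_s, draft_seq, corr_seq, ref_adp,
             reg_adp, score, read_adp, status, orig_pos) = row
            if etype not in ERROR_TYPES:
                raise ValueError(f"{path}:{line_no}: unknown error_type {etype!r}")
            if status not in STATUSES:
                raise ValueError(f"{path}:{line_no}: unknown status {status!r}")
            try:
                position = int(pos_s) - 1
            except ValueError:
                raise ValueError(f"{path}:{line_no}: non-integer position {pos_s!r}")
            errors.append(CandidateError(
                contig=contig, position=position, error_type=etype,
                length=int(length_s),
                draft_seq="" if draft_seq == "." else draft_seq,
                correction_seq="" if corr_seq == "." else corr_seq,
                reference_adp=float(ref_adp), regional_adp=float(reg_adp),
                score=float(score),
                read_adp=None if read_adp == "." else float(read_adp),
                status=status,
                original_position=None if orig_pos == "." else int(orig_pos) - 1,
            ))
    return errors
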