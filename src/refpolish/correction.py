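"""Applying a finalized error list to the draft assembly.

Every position in an error list refers to the *original* draft
coordinates.  Edits are applied per contig in descending coordinate order
so earlier coordinates never shift, which also makes the correction
reproducible from the TSV alone.  Overlapping or duplicate edits signal a
corrupt list and are rejected rather than merged.
"""

from __future__ import annotations

import os
from pathlib import Path

from .io import read_error_table, read_fasta, write_fasta
from .model import (
    CandidateError,
    DELETION,
    INSERTION,
    SUBSTITUTION,
    sort_errors,
)


def _affected_interval(error: CandidateError) -> tuple[int, int]:
    """Half-open draft interval an edit touches; deletion errors occupy the
    zero-width point after their anchor."""
    if error.error_type == DELETION:
        return error.position + 1, error.position + 1
    return error.position, error.position + error.length


def _check_overlaps(errors: list[CandidateError]) -> None:
    by_contig: dict[str, list] = {}
    for e in errors:
        by_contig.setdefault(e.contig, []).append(e)
    for contig, group in by_contig.items():
        ivals = sorted(((*_affected_interval(e), e) for e in group),
                       key=lambda t: (t[0], t[1]))
        for (s1, e1, a), (s2, e2, b) in zip(ivals, ivals[1:]):
            if (s1, e1) == (s2, e2) or s2 < e1:
                raise ValueError(
                    f"overlapping edits on {contig}: "
                    f"{a.error_type}@{a.position + 1} and "
                    f"{b.error_type}@{b.position + 1}"
                )


def apply_errors(draft: dict[str, str],
                 errors: list[CandidateError]) -> dict[str, str]:
    """Return the corrected assembly.

    Substitutions replace ``length`` draft bases with the correction;
    insertion errors delete their spurious draft bases; deletion errors
    insert the missing bases after the anchor (anchor -1 prepends).
    ``removed`` candidates are skipped.  A draft-sequence mismatch at an
    edit site means the list is stale and raises.
    """
    applicable = [e for e in errors if e.applicable]
    _check_overlaps(applicable)
    corrected = dict(draft)
    by_contig: dict[str, list[CandidateError]] = {}
    for e in applicable:
        if e.contig not in draft:
            raise ValueError(f"error list names unknown contig {e.contig!r}")
        by_contig.setdefault(e.contig, []).append(e)
    for contig, group in by_contig.items():
        seq = draft[contig]
        # descending by affected coordinate: earlier edits never shift
        group.sort(key=lambda e: _affected_interval(e)[0], reverse=True)
        for e in group:
            if e.error_type == DELETION:
                if not -1 <= e.position < len(seq):
                    raise ValueError(f"deletion anchor outside {contig}: "
                                     f"{e.position + 1}")
                cut = e.position + 1
                seq = seq[:cut] + e.correction_seq + seq[cut:]
                continue
            found = seq[e.position:e.position + e.length]
            if found != e.draft_seq:
                raise ValueError(
                    f"stale error list: draft has {found!r} at "
                    f"{contig}:{e.position + 1}, expected {e.draft_seq!r}"
                )
            repl = e.correction_seq if e.error_type == SUBSTITUTION else ""
            seq = seq[:e.position] + repl + seq[e.position + e.length:]
        corrected[contig] = seq
    return corrected


def invert_errors(errors: list[CandidateError]) -> list[CandidateError]:
    """Edit list that undoes ``errors`` on the corrected assembly.

    Insertion and deletion roles swap and draft/correction sequences swap;
    positions are re-expressed in corrected-assembly coordinates.
    """
    from dataclasses import replace

    inverted: list[CandidateError] = []
    by_contig: dict[str, list[CandidateError]] = {}
    for e in sort_errors([e for e in errors if e.applicable]):
        by_contig.setdefault(e.contig, []).append(e)
    for contig, group in by_contig.items():
        group.sort(key=lambda e: _affected_interval(e)[0])
        shift = 0
        for e in group:
            if e.error_type == SUBSTITUTION:
                inverted.append(replace(
                    e, position=e.position + shift,
                    draft_seq=e.correction_seq, correction_seq=e.draft_seq,
                    original_position=None))
            elif e.error_type == INSERTION:
                # forward deleted draft bases; inverse re-inserts them
                inverted.append(CandidateError(
                    contig=contig, position=e.position + shift - 1,
                    error_type=DELETION, length=e.length, draft_seq="",
                    correction_seq=e.draft_seq, status=e.status))
                shift -= e.length
            else:
                inverted.append(CandidateError(
                    contig=contig, position=e.position + shift + 1,
                    error_type=INSERTION, length=e.length,
                    draft_seq=e.correction_seq, correction_seq="",
                    status=e.status))
                shift += e.length
    return sort_errors(inverted)


def reapply_from_table(draft_path: str | os.PathLike,
                       table_path: str | os.PathLike,
                       out_path: str | os.PathLike) -> dict[str, str]:
    """Reproduce the corrected FASTA from the draft and an error-list TSV.

    Output is byte-identical to the FASTA written by the pipeline run that
    produced the table.  On any failure no partial output file is left
    behind (written via a temporary file and renamed).
    """
    out_path = Path(out_path)
    draft = read_fasta(draft_path)
    errors = read_error_table(table_path)
    corrected = apply_errors(draft, errors)
    tmp = out_path.with_name(out_path.name + ".tmp")
    try:
        write_fasta(corrected, tmp)
        os.replace(tmp, out_path)
    finally:
        tmp.unlink(missing_ok=True)
    return corrected
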