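"""Homopolymer-run utilities.

Nanopore indel errors cluster in runs of identical nucleotides, so several
stages need the maximal run containing a position: the pass-2 detection
window, the site score weight, and the grouping of read evidence.
"""

from __future__ import annotations

from .model import HomopolymerContext


def run_at(seq: str, pos: int) -> HomopolymerContext:
    """Maximal run of identical bases in ``seq`` containing ``pos``."""
    if not 0 <= pos < len(seq):
        raise IndexError(f"position {pos} outside sequence of length {len(seq)}")
    base = seq[pos]
    start = pos
    while start > 0 and seq[start - 1] == base:
        start -= 1
    end = pos + 1
    while end < len(seq) and seq[end] == base:
        end += 1
    return HomopolymerContext(base=base, start=start, end=end)


def run_ending_at(seq: str, pos: int) -> HomopolymerContext:
    """Maximal run whose last base is at ``pos`` or earlier (run ending at
    ``pos`` inclusive); used for 'upstream homopolymer' profiling."""
    return run_at(seq, pos)


def insertion_run(seq: str, anchor: int, inserted: str) -> HomopolymerContext | None:
    """Run of the would-be-inserted base adjacent to a deletion-error site.

    A deletion error anchored at ``anchor`` inserts ``inserted`` after that
    draft base.  When the inserted sequence is a single repeated base that
    extends an adjacent run, any anchor along that run yields the same
    corrected sequence; the returned run defines the equivalence class.
    Returns None when the insertion does not extend an adjacent run.
    """
    if not inserted or len(set(inserted)) != 1:
        return None
    base = inserted[0]
    if 0 <= anchor < len(seq) and seq[anchor] == base:
        return run_at(seq, anchor)
    if 0 <= anchor + 1 < len(seq) and seq[anchor + 1] == base:
        return run_at(seq, anchor + 1)
    return None


def splits_run(seq: str, anchor: int, inserted: str) -> bool:
    """True when inserting ``inserted`` after ``anchor`` would place a
    non-matching base strictly inside a run of length >= 2."""
    if anchor < 0 or anchor + 1 >= len(seq):
        return False
    left, right = seq[anchor], seq[anchor + 1]
    if left != right:
        return False
    return any(b != left for b in inserted)


def substitution_splits_run(seq: str, pos: int) -> bool:
    """True when replacing the base at ``pos`` breaks a run in two (the
    position lies strictly inside a run, not at either edge)."""
    run = run_at(seq, pos)
    return run.start < pos < run.end - 1
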