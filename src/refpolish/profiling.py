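"""Sequence-context profiling of a final error list.

Nanopore basecallers emit k-mer events, so assembly errors concentrate
after characteristic upstream contexts -- above all homopolymers.  These
profiles tabulate, per error type, the draft 4-mer immediately upstream of
each error (keyed with the erroneous nucleotide) and the length of the
maximal run ending just upstream.  "Upstream" is taken on the draft's
forward strand as stored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .homopolymer import run_at
from .model import CandidateError, DELETION


@dataclass(slots=True)
class KmerProfile:
    """Counts keyed by ``(error_type, upstream_kmer, erroneous_base)``."""

    k: int
    counts: Counter = field(default_factory=Counter)
    excluded: int = 0  # errors too close to a contig start to have a k-mer

    def total(self) -> int:
        return sum(self.counts.values())


def _erroneous_base(error: CandidateError) -> str:
    """First affected base: from the draft for insertions/substitutions,
    from the correction for deletions (the draft lacks the base)."""
    seq = error.correction_seq if error.error_type == DELETION else error.draft_seq
    return seq[0]


def _site_start(error: CandidateError) -> int:
    """Draft coordinate of the first erroneous position; for a deletion the
    missing bases sit just after the anchor."""
    if error.error_type == DELETION:
        return error.position + 1
    return error.position


def upstream_kmer_profile(errors: list[CandidateError], draft: dict[str, str],
                          k: int = 4) -> KmerProfile:
    """Exact, order-independent tally of upstream k-mers per error type.

    Errors closer than ``k`` to their contig start have no full upstream
    k-mer and are counted in ``excluded`` instead.
    """
    profile = KmerProfile(k=k)
    for error in errors:
        pos = _site_start(error)
        if pos < k:
            profile.excluded += 1
            continue
        kmer = draft[error.contig][pos - k:pos]
        profile.counts[(error.error_type, kmer, _erroneous_base(error))] += 1
    return profile


def homopolymer_length_distribution(errors: list[CandidateError],
                                    draft: dict[str, str],
                                    include_site: bool = False,
                                    ) -> dict[str, Counter]:
    """Histogram of upstream homopolymer lengths per error type.

    The upstream homopolymer is the maximal run ending at the position just
    before the error site (length >= 1 always).  With ``include_site`` the
    run containing the first erroneous position is measured instead.
    """
    hist: dict[str, Counter] = {}
    for error in errors:
        seq = draft[error.contig]
        pos = _site_start(error)
        anchor = pos if include_site else pos - 1
        if not 0 <= anchor < len(seq):
            continue
        length = run_at(seq, anchor).length
        hist.setdefault(error.error_type, Counter())[length] += 1
    return hist


def profile_table(profile: KmerProfile, top: int | None = None) -> list[tuple]:
    """Rows ``(error_type, kmer, erroneous_base, count)`` sorted by
    descending count then key; optionally truncated per error type."""
    rows = sorted(profile.counts.items(), key=lambda kv: (kv[0][0], -kv[1], kv[0]))
    out: list[tuple] = []
    per_type: Counter = Counter()
    for (etype, kmer, base), count in rows:
        per_type[etype] += 1
        if top is not None and per_type[etype] > top:
            continue
        out.append((etype, kmer, base, count))
    return out


def write_profile_tsv(profile: KmerProfile, hist: dict[str, Counter],
                      path) -> None:
    """Write both profiles as one small TSV summary."""
    with open(path, "w") as fh:
        fh.write("section\terror_type\tkey\terroneous_base\tcount\n")
        for etype, kmer, base, count in profile_table(profile):
            fh.write(f"kmer\t{etype}\t{kmer}\t{base}\t{count}\n")
        for etype in sorted(hist):
            for length in sorted(hist[etype]):
                fh.write(f"homopolymer\t{etype}\t{length}\t.\t{hist[etype][length]}\n")
        fh.write(f"excluded\tall\t.\t.\t{profile.excluded}\n")
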