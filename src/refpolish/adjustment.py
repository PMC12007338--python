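"""Read-based confirmation, repositioning, splitting and removal of
reference-detected candidates.

Reference genomes carry strain variation, so a reference-detected candidate
may sit a few bases off the true error, or not be an error at all.  This
stage re-evaluates every candidate against a pileup of the raw reads (the
only evidence specific to the sequenced strain) inside a 21 nt window
centred on the candidate.  Indel candidates are never dropped for lack of
read support -- systematic homopolymer miscalls mean true indel errors can
be poorly supported by reads -- they are confirmed, relocated, split into
two single-base indels, or retained unadjusted.  Substitution candidates
by contrast *require* read support and are removed without it.

Read evidence inside one homopolymer run is pooled into a single
representative site (every anchor along a run implies the same corrected
sequence); the canonical representative is the run-end anchor.  An event
that would break a run apart is kept as its own independent site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from .config import PolishConfig
from .homopolymer import insertion_run, run_at
from .model import (
    CandidateError,
    DELETION,
    INSERTION,
    Pileup,
    SUBSTITUTION,
    ST_ADJUSTED,
    ST_CONFIRMED,
    ST_REMOVED,
    ST_RETAINED,
    ST_SPLIT,
    sort_errors,
)


@dataclass(slots=True)
class ProfileSite:
    """Pooled read evidence for one representative candidate site."""

    position: int  # canonical position (site for insertions, anchor for deletions)
    adp: float
    support: int  # distinct supporting reads
    depth: int  # reads covering the representative site
    alt_counts: Counter = field(default_factory=Counter)
    member_positions: set[int] = field(default_factory=set)


def _site_key(draft_seq: str, position: int, error_type: str, length: int,
              inserted: str = "") -> tuple[object, int]:
    """Group key and canonical position for one indel evidence site.

    Insertion errors: spurious bases lying inside one run group along it,
    canonical site = the run's last ``length`` bases.  Deletion errors:
    insertions extending an adjacent run group along it, canonical anchor =
    the run's last base; run-breaking insertions stay independent.
    """
    if error_type == INSERTION:
        spurious = draft_seq[position:position + length]
        if spurious and len(set(spurious)) == 1:
            run = run_at(draft_seq, position)
            if run.length >= length:
                return (run.start, run.end), run.end - length
        return ("pos", position), position
    run = insertion_run(draft_seq, position, inserted)
    if run is not None:
        return (run.start, run.end), run.end - 1
    return ("pos", position), position


def read_adp_profile(read_pileup_columns, draft_seq: str,
                     window: tuple[int, int], error_type: str, length: int,
                     ) -> dict[object, ProfileSite]:
    """Per-site read ADP for one indel error type/length across a window.

    Returns a map of group key -> :class:`ProfileSite`; empty when no read
    covers the window.  Denominators are the reads covering each group's
    representative site (gap placeholders count as covering).
    """
    sites: dict[object, ProfileSite] = {}
    reads_per_key: dict[object, set[int]] = {}
    start, end = window
    for pos in range(start, end):
        for obs in read_pileup_columns[pos].observations:
            if error_type == INSERTION:
                if len(obs.deletion) != length:
                    continue
                key, canon = _site_key(draft_seq, pos + 1, error_type, length)
                member, alt = pos + 1, len(obs.deletion)
            else:
                if len(obs.insertion) != length:
                    continue
                key, canon = _site_key(draft_seq, pos, error_type, length,
                                       obs.insertion)
                member, alt = pos, obs.insertion
            seen = reads_per_key.setdefault(key, set())
            site = sites.get(key)
            if site is None:
                site = sites[key] = ProfileSite(position=canon, adp=0.0,
                                                support=0, depth=0)
            site.member_positions.add(member)
            if obs.source not in seen:
                seen.add(obs.source)
                site.support += 1
                site.alt_counts[alt] += 1
    for key, site in sites.items():
        ref_pos = min(max(site.position, 0), len(read_pileup_columns) - 1)
        site.depth = read_pileup_columns[ref_pos].depth
        site.adp = site.support / site.depth if site.depth else 0.0
    return sites


def _adjust_window(position: int, contig_len: int,
                   config: PolishConfig) -> tuple[int, int]:
    half = config.adjust_window // 2
    return max(0, position - half), min(contig_len, position + half + 1)


def _rederive(candidate: CandidateError, site: ProfileSite, draft_seq: str,
              status: str) -> CandidateError:
    """Place a candidate at a read-supported site, re-deriving its
    sequences from the read evidence there."""
    pos = site.position
    if candidate.error_type == INSERTION:
        length = candidate.length
        draft_bases, correction = draft_seq[pos:pos + length], ""
    else:
        best = max(site.alt_counts.values())
        correction = min(s for s, n in site.alt_counts.items() if n == best)
        length = len(correction)
        draft_bases = ""
    if pos == candidate.position:
        out = candidate
        if status == ST_ADJUSTED:
            status = ST_CONFIRMED
    else:
        out = candidate.moved_to(pos)
    return replace(out, status=status, read_adp=site.adp, length=length,
                   draft_seq=draft_bases, correction_seq=correction)


def adjust_indel(candidate: CandidateError, read_pileup: Pileup,
                 config: PolishConfig, draft: dict[str, str],
                 ) -> list[CandidateError]:
    """Confirm, relocate, split or retain one indel candidate.

    The initial site is assessed first: with read support at or above the
    adjustment threshold no alternative is considered (the position is
    snapped to the run's canonical anchor, an equivalent edit).  Otherwise
    the best-supported same-type same-length site in the window replaces
    it; failing that, a 2 nt candidate may split into two supported 1 nt
    candidates; failing everything the candidate is retained unadjusted.
    """
    if candidate.error_type not in (INSERTION, DELETION):
        raise ValueError("adjust_indel only handles indel candidates")
    seq = draft[candidate.contig]
    cols = read_pileup.contigs[candidate.contig]
    if not 0 <= candidate.position < len(seq):
        raise ValueError(f"candidate window outside contig at "
                         f"{candidate.contig}:{candidate.position + 1}")
    window = _adjust_window(candidate.position, len(seq), config)
    profile = read_adp_profile(cols, seq, window, candidate.error_type,
                               candidate.length)

    own_key, _ = _site_key(seq, candidate.position, candidate.error_type,
                           candidate.length, candidate.correction_seq)
    own = profile.get(own_key)
    if own is not None and own.adp >= config.adjust_threshold_indel:
        status = ST_CONFIRMED if own.position == candidate.position else ST_ADJUSTED
        return [_rederive(candidate, own, seq, status)]

    supported = sorted((s for s in profile.values()
                        if s.adp >= config.adjust_threshold_indel),
                       key=lambda s: (-s.adp, s.position))
    if supported:
        return [_rederive(candidate, supported[0], seq, ST_ADJUSTED)]

    if candidate.length == 2:
        profile1 = read_adp_profile(cols, seq, window, candidate.error_type, 1)
        singles = sorted((s for s in profile1.values()
                          if s.adp >= config.adjust_threshold_indel),
                         key=lambda s: (-s.adp, s.position))
        if len(singles) >= 2:
            halves = []
            for site in singles[:2]:
                half = replace(candidate, length=1,
                               draft_seq=candidate.draft_seq[:1] or "",
                               correction_seq=candidate.correction_seq[:1] or "")
                halves.append(_rederive(half, site, seq, ST_SPLIT))
                halves[-1] = replace(halves[-1], status=ST_SPLIT,
                                     original_position=candidate.position)
            return sorted(halves, key=lambda e: e.position)

    return [replace(candidate, status=ST_RETAINED,
                    read_adp=own.adp if own is not None else 0.0)]


def confirm_substitution(candidate: CandidateError, read_pileup: Pileup,
                         config: PolishConfig, draft: dict[str, str],
                         ) -> CandidateError:
    """Pick the best read-supported replacement base or remove the
    candidate; raw unfiltered reads are the evidence."""
    if candidate.error_type != SUBSTITUTION:
        raise ValueError("confirm_substitution only handles substitutions")
    col = read_pileup.contigs[candidate.contig][candidate.position]
    counts = Counter()
    for obs in col.observations:
        if obs.kind == "mismatch" and obs.base not in ("N", candidate.draft_seq):
            counts[obs.base] += 1
    if col.depth == 0 or not counts:
        return replace(candidate, status=ST_REMOVED, read_adp=0.0)
    best_n = max(counts.values())
    base = min(b for b, n in counts.items() if n == best_n)
    adp = best_n / col.depth
    if adp >= config.adjust_threshold_sub:
        return replace(candidate, status=ST_CONFIRMED, correction_seq=base,
                       read_adp=adp)
    return replace(candidate, status=ST_REMOVED, read_adp=adp)


def adjust_all(candidates: list[CandidateError],
               read_pileup: Pileup | None, config: PolishConfig,
               draft: dict[str, str]) -> list[CandidateError]:
    """Apply read adjustment to a whole candidate list.

    Without a read pileup every substitution candidate is removed (no
    strain-specific evidence can confirm a replacement base) while indel
    candidates pass through unadjusted.  Removed candidates stay in the
    list for the report but are never applied by the corrector.
    """
    out: list[CandidateError] = []
    if read_pileup is None:
        for cand in candidates:
            if cand.error_type == SUBSTITUTION:
                out.append(replace(cand, status=ST_REMOVED))
            else:
                out.append(replace(cand, status=ST_RETAINED))
        return sort_errors(out)
    read_pileup.validate_against(draft)
    for cand in candidates:
        if cand.error_type == SUBSTITUTION:
            out.append(confirm_substitution(cand, read_pileup, config, draft))
        else:
            out.extend(adjust_indel(cand, read_pileup, config, draft))
    return sort_errors(out)
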