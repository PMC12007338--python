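"""Candidate error detection from the reference pileup.

The detector scans every draft position over a multi-pass window schedule.
At each sufficiently covered column it computes an alignment difference
probability (ADP) per error type: the fraction of covering reference
genomes whose alignment disagrees with the draft at that site.  Columns
whose best positional ADP reaches the regional trigger are expanded to the
pass window, where a regional ADP counts each reference at most once no
matter how many differences it shows.  Regions reaching the error
threshold are scored per site as ``mismatch frequency x homopolymer
length`` (halved when the implied correction would split a run) and the
best-scoring site is emitted as a candidate error.

Error types are named from the draft's perspective: a *deletion* event on a
reference (the reference lacks draft bases) is evidence for an *insertion*
error in the draft, and a reference *insertion* is evidence for a draft
*deletion* error.  Indels longer than ``max_indel_len`` are regarded as
strain variants and ignored outright; 1 nt and 2 nt indels are tallied as
independent errors, except on strategy-enabled elective passes where the
lengths may be merged when references disagree on length alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .config import PolishConfig
from .homopolymer import insertion_run, run_at, splits_run, substitution_splits_run
from .model import (
    CandidateError,
    DELETION,
    INSERTION,
    Pileup,
    PileupColumn,
    SUBSTITUTION,
    sort_errors,
)


# ---------------------------------------------------------------------------
# per-column summaries

@dataclass(slots=True)
class ColumnSummary:
    """Positional difference tallies for one pileup column."""

    depth: int = 0
    sub_bases: Counter = field(default_factory=Counter)  # alt base -> #refs
    ins_by_len: Counter = field(default_factory=Counter)  # draft-spurious length -> #refs
    del_seqs: dict[int, Counter] = field(default_factory=dict)  # length -> seq -> #refs

    @property
    def sub_count(self) -> int:
        return sum(self.sub_bases.values())

    def ins_count(self, length: int | None) -> int:
        if length is None:
            return sum(self.ins_by_len.values())
        return self.ins_by_len[length]

    def del_count(self, length: int | None) -> int:
        lens = self.del_seqs if length is None else [length]
        return sum(sum(self.del_seqs[L].values()) for L in lens if L in self.del_seqs)

    def count(self, error_type: str, length: int | None = None) -> int:
        if error_type == SUBSTITUTION:
            return self.sub_count
        if error_type == INSERTION:
            return self.ins_count(length)
        return self.del_count(length)


def summarize_column(column: PileupColumn, max_indel_len: int) -> ColumnSummary:
    summary = ColumnSummary(depth=column.depth)
    count_subs = column.draft_base != "N"
    for obs in column.observations:
        if count_subs and obs.kind == "mismatch" and obs.base != "N":
            summary.sub_bases[obs.base] += 1
        if obs.deletion and len(obs.deletion) <= max_indel_len:
            summary.ins_by_len[len(obs.deletion)] += 1
        if obs.insertion and len(obs.insertion) <= max_indel_len:
            L = len(obs.insertion)
            summary.del_seqs.setdefault(L, Counter())[obs.insertion] += 1
    return summary


def positional_adp(column: PileupColumn, error_type: str,
                   max_indel_len: int = 2) -> tuple[float, dict]:
    """Positional ADP for one error type at one column.

    Returns the fraction of covering references exhibiting the difference,
    plus per-alternative details: alternative-base counts for
    substitutions, per-length counts for insertion errors, and per-length
    inserted-sequence counts for deletion errors.  Events longer than
    ``max_indel_len`` never contribute.  Depth-zero columns are the
    caller's responsibility (coverage gate).
    """
    if column.depth == 0:
        raise ValueError("positional ADP undefined at zero depth; gate coverage first")
    s = summarize_column(column, max_indel_len)
    if error_type == SUBSTITUTION:
        return s.sub_count / s.depth, dict(s.sub_bases)
    if error_type == INSERTION:
        return s.ins_count(None) / s.depth, dict(s.ins_by_len)
    if error_type == DELETION:
        return s.del_count(None) / s.depth, {L: dict(c) for L, c in s.del_seqs.items()}
    raise ValueError(f"unknown error type {error_type!r}")


def coverage_gate(column: PileupColumn, min_ref_coverage: int) -> bool:
    """True when the column has enough covering references to assess."""
    return column.depth >= min_ref_coverage


# ---------------------------------------------------------------------------
# window schedule

def window_schedule(pass_index: int, draft_seq: str, position: int,
                    config: PolishConfig) -> tuple[int, int]:
    """Half-open window for one scan pass, truncated at contig ends.

    Pass 1 is the single candidate column; pass 2 spans the maximal
    homopolymer run containing the column; elective passes use a centred
    window starting at ``third_pass_window`` nt and growing by
    ``window_growth`` nt per side per pass.
    """
    if not 1 <= pass_index <= config.total_passes:
        raise ValueError(f"pass {pass_index} outside schedule "
                         f"(1..{config.total_passes})")
    if pass_index == 1:
        return position, position + 1
    if pass_index == 2:
        run = run_at(draft_seq, position)
        return run.start, run.end
    half = (config.third_pass_window // 2
            + config.window_growth * (pass_index - 3))
    return max(0, position - half), min(len(draft_seq), position + half + 1)


def strategies_enabled(pass_index: int, config: PolishConfig) -> bool:
    """Window shifting and alternative-length merging run on every
    ``strategy_every``-th elective pass (passes 4, 6, ... by default)."""
    elective_ordinal = pass_index - 2
    return elective_ordinal >= 1 and elective_ordinal % config.strategy_every == 0


# ---------------------------------------------------------------------------
# regional ADP

def _qualifies(obs, error_type: str, length: int | None, max_indel_len: int) -> bool:
    if error_type == SUBSTITUTION:
        return obs.kind == "mismatch" and obs.base != "N"
    if error_type == INSERTION:
        n = len(obs.deletion)
        return 0 < n <= max_indel_len and (length is None or n == length)
    n = len(obs.insertion)
    return 0 < n <= max_indel_len and (length is None or n == length)


def regional_adp(columns: list[PileupColumn], window: tuple[int, int],
                 error_type: str, config: PolishConfig, trigger_pos: int,
                 length: int | None = None) -> tuple[float, set[int]]:
    """Window-level ADP where each aligned source counts at most once.

    The denominator is the set of sources covering the *trigger* column
    (reference blocks may end mid-window); the numerator is the subset of
    those sources showing at least one qualifying difference of the given
    type (and length, when fixed) anywhere in the window.
    """
    covering = {o.source for o in columns[trigger_pos].observations}
    if not covering:
        raise ValueError("regional ADP undefined with no covering sources")
    contributing: set[int] = set()
    start, end = window
    skip_subs = error_type == SUBSTITUTION
    for pos in range(start, end):
        if skip_subs and columns[pos].draft_base == "N":
            continue
        for obs in columns[pos].observations:
            if obs.source in covering and obs.source not in contributing \
                    and _qualifies(obs, error_type, length, config.max_indel_len):
                contributing.add(obs.source)
    return len(contributing) / len(covering), contributing


# ---------------------------------------------------------------------------
# region scoring

@dataclass(slots=True)
class _Site:
    position: int  # candidate coordinate (site for sub/ins, anchor for del)
    sources: set[int]
    alt_counts: Counter  # sub: base -> n ; del: inserted seq -> n ; ins: length -> n


def _collect_sites(columns, draft_seq, window, error_type, length, max_indel_len):
    sites: dict[int, _Site] = {}
    start, end = window
    for pos in range(start, end):
        for obs in columns[pos].observations:
            if not _qualifies(obs, error_type, length, max_indel_len):
                continue
            if error_type == SUBSTITUTION:
                if columns[pos].draft_base == "N":
                    continue
                key, alt = pos, obs.base
            elif error_type == INSERTION:
                key, alt = pos + 1, len(obs.deletion)  # first spurious draft base
            else:
                key, alt = pos, obs.insertion  # anchor of the missing bases
            site = sites.setdefault(key, _Site(key, set(), Counter()))
            if obs.source not in site.sources:
                site.sources.add(obs.source)
                site.alt_counts[alt] += 1
    return sorted(sites.values(), key=lambda s: s.position)


def _group_key(site: _Site, draft_seq: str, error_type: str):
    if error_type in (SUBSTITUTION, INSERTION):
        if site.position >= len(draft_seq):
            return ("pos", site.position)
        run = run_at(draft_seq, site.position)
        return (run.start, run.end)
    seq = site.alt_counts.most_common(1)[0][0]
    run = insertion_run(draft_seq, site.position, seq)
    if run is None:
        return ("pos", site.position)
    return (run.start, run.end)


def score_region(columns: list[PileupColumn], draft_seq: str, contig: str,
                 window: tuple[int, int], error_type: str,
                 config: PolishConfig, length: int | None = None,
                 ) -> CandidateError | None:
    """Score every in-window location carrying a same-type reference
    difference and return the best-scoring candidate error.

    Locations within one homopolymer run and of the same correction type
    are merged (supports deduplicated per reference) before scoring;
    score = per-site reference fraction x homopolymer length, halved when
    the implied correction would break a run apart.  Ties go to the
    leftmost site.  Returns None when the window holds no scorable site.
    """
    sites = _collect_sites(columns, draft_seq, window, error_type, length,
                           config.max_indel_len)
    if not sites:
        return None

    groups: dict[object, list[_Site]] = {}
    for site in sites:
        groups.setdefault(_group_key(site, draft_seq, error_type), []).append(site)

    best = None  # (score, rep_position, candidate)
    for members in groups.values():
        sources: set[int] = set()
        alts: Counter = Counter()
        for m in members:
            sources |= m.sources
            alts.update(m.alt_counts)
        rep = max(members, key=lambda m: (len(m.sources), -m.position))
        depth = columns[min(rep.position, len(columns) - 1)].depth
        if depth == 0:
            continue
        freq = len(sources) / depth

        if error_type == SUBSTITUTION:
            pos = rep.position
            run_len = run_at(draft_seq, pos).length
            base = min(b for b, n in alts.items() if n == max(alts.values()))
            draft_bases, correction, err_len = draft_seq[pos], base, 1
            penalized = substitution_splits_run(draft_seq, pos) and run_len >= 2
        elif error_type == INSERTION:
            pos = rep.position
            if length is None:
                best_n = max(alts.values())
                err_len = min(L for L, n in alts.items() if n == best_n)
            else:
                err_len = length
            err_len = min(err_len, len(draft_seq) - pos)
            if err_len < 1:
                continue
            run_len = run_at(draft_seq, pos).length
            draft_bases, correction = draft_seq[pos:pos + err_len], ""
            penalized = False
        else:  # deletion error
            pos = rep.position
            candidates = ({s: n for s, n in alts.items() if len(s) == length}
                          if length is not None else dict(alts))
            if not candidates:
                continue
            best_n = max(candidates.values())
            correction = min(s for s, n in candidates.items() if n == best_n)
            err_len = len(correction)
            run = insertion_run(draft_seq, pos, correction)
            run_len = run.length if run is not None else 1
            draft_bases = ""
            penalized = splits_run(draft_seq, pos, correction)

        score = freq * run_len
        if penalized:
            score *= 0.5
        cand = CandidateError(
            contig=contig, position=pos, error_type=error_type,
            length=err_len, draft_seq=draft_bases, correction_seq=correction,
            reference_adp=freq, score=score,
        )
        key = (-score, pos)
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1] if best is not None else None


# ---------------------------------------------------------------------------
# the multi-pass scan

def _max_positional_adp(summaries: list[ColumnSummary], min_cov: int) -> np.ndarray:
    out = np.zeros(len(summaries))
    for i, s in enumerate(summaries):
        if s.depth < min_cov:
            continue
        best = max(s.sub_count, s.ins_count(None), s.del_count(None))
        out[i] = best / s.depth
    return out


def _spec_list(config: PolishConfig, merge_lengths: bool):
    specs: list[tuple[str, int | None]] = [(SUBSTITUTION, None)]
    for L in range(1, config.max_indel_len + 1):
        specs.append((DELETION, L))
    for L in range(1, config.max_indel_len + 1):
        specs.append((INSERTION, L))
    if merge_lengths and config.max_indel_len > 1:
        specs.append((DELETION, None))
        specs.append((INSERTION, None))
    return specs


def detect(ref_pileup: Pileup, draft: dict[str, str], config: PolishConfig,
           secondary_pileup: Pileup | None = None) -> list[CandidateError]:
    """Run the full multi-pass scan and emit scored candidate errors.

    Columns covered by fewer than ``min_ref_coverage`` primary references
    are re-evaluated against the secondary pileup when one is supplied
    (low-coverage supplementation).  Columns inside an emitted candidate's
    window are claimed and skipped in later passes: simple cases are fixed
    early and never revised.  Output is sorted and deterministic.
    """
    ref_pileup.validate_against(draft)
    if secondary_pileup is not None:
        secondary_pileup.validate_against(draft)

    candidates: list[CandidateError] = []
    for contig, seq in draft.items():
        cols = ref_pileup.contigs[contig]
        summaries = [summarize_column(c, config.max_indel_len) for c in cols]
        trigger_ok = _max_positional_adp(summaries, config.min_ref_coverage) \
            >= config.regional_trigger
        sec_cols = sec_summaries = None
        if secondary_pileup is not None:
            sec_cols = secondary_pileup.contigs[contig]
            sec_summaries = [summarize_column(c, config.max_indel_len)
                             for c in sec_cols]
            sec_ok = _max_positional_adp(sec_summaries, config.min_ref_coverage) \
                >= config.regional_trigger
            primary_gated = np.array([s.depth < config.min_ref_coverage
                                      for s in summaries])
            trigger_ok |= primary_gated & sec_ok

        # claims are per error type: a combined substitution + deletion at
        # one site must still surface as two adjacent candidates
        claimed = {etype: np.zeros(len(seq), dtype=bool)
                   for etype in (SUBSTITUTION, INSERTION, DELETION)}
        for pass_index in range(1, config.total_passes + 1):
            with_strategies = strategies_enabled(pass_index, config)
            specs = _spec_list(config, with_strategies)
            open_cols = trigger_ok & ~(claimed[SUBSTITUTION]
                                       & claimed[INSERTION]
                                       & claimed[DELETION])
            for c in np.flatnonzero(open_cols):
                c = int(c)
                if summaries[c].depth >= config.min_ref_coverage:
                    use_cols, use_sum = cols, summaries[c]
                elif sec_summaries is not None \
                        and sec_summaries[c].depth >= config.min_ref_coverage:
                    use_cols, use_sum = sec_cols, sec_summaries[c]
                else:
                    continue
                depth = use_sum.depth
                window = window_schedule(pass_index, seq, c, config)
                width = window[1] - window[0]
                windows = [window]
                if with_strategies and width > 1:
                    windows.append((max(0, c - width + 1), c + 1))
                    windows.append((c, min(len(seq), c + width)))
                best = None  # (reg_adp, -spec_order, window, etype, L)
                for order, (etype, L) in enumerate(specs):
                    if claimed[etype][c]:
                        continue
                    if use_sum.count(etype, L) / depth < config.regional_trigger:
                        continue
                    for w in windows:
                        reg, _ = regional_adp(use_cols, w, etype, config, c, L)
                        key = (reg, -order)
                        if best is None or key > best[0]:
                            best = (key, w, etype, L)
                if best is None or best[0][0] < config.error_threshold:
                    continue
                _, win, etype, L = best
                cand = score_region(use_cols, seq, contig, win, etype, config, L)
                if cand is None or claimed[etype][min(cand.position, len(seq) - 1)]:
                    continue
                cand.regional_adp = best[0][0]
                cand.pass_found = pass_index
                candidates.append(cand)
                claimed[etype][win[0]:win[1]] = True
                claimed[etype][min(cand.position, len(seq) - 1)] = True
    return sort_errors(candidates)
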