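"""Seeded synthetic test worlds: truth genome, error-injected draft,
divergent references, simulated reads -- serialized as FASTA + mpileup.

The generator emulates the data regime the polisher targets: a small
genome whose draft carries sparse 1-2 nt indel errors (homopolymer-biased,
deletions dominating) and substitutions, compared against ~10 reference
genomes at strain-level divergence, with long raw reads whose own errors
are substitutions plus homopolymer-length miscalls that escalate with run
length.  Alignments of references and reads to the draft are computed
*exactly* from the known edit coordinates -- no heuristic aligner is
involved -- then serialized in the all-positions mpileup dialect, so every
other module is testable without external tools or downloads.

Reference divergence events never coincide with (or come near) injected
error sites, keeping the ground truth unambiguous; homopolymer indels are
canonically anchored at the end of their run.  All sampling goes through
one named, seeded generator: the same seed yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .correction import apply_errors
from .homopolymer import insertion_run, run_at
from .model import (
    CandidateError,
    DELETION,
    INSERTION,
    Observation,
    Pileup,
    PileupColumn,
    SUBSTITUTION,
)
from .io import write_error_table, write_fasta, write_mpileup

_BASES = "ACGT"


@dataclass(frozen=True, slots=True)
class ErrorSpec:
    """One error to inject into the draft.

    ``placement`` is ``random``, ``after_kmer`` (requires ``kmer``) or
    ``in_homopolymer`` (requires ``min_run``).
    """

    error_type: str
    length: int = 1
    placement: str = "random"
    kmer: str = ""
    min_run: int = 3


def default_error_mix(n: int = 50) -> list[ErrorSpec]:
    """A draft-error mix shaped like long-read assemblies: mostly 1 nt
    homopolymer deletions, fewer insertions, some substitutions."""
    mix: list[ErrorSpec] = []
    for i in range(n):
        r = i % 10
        if r < 4:
            mix.append(ErrorSpec(DELETION, 1, "in_homopolymer", min_run=3))
        elif r < 5:
            mix.append(ErrorSpec(DELETION, 2, "in_homopolymer", min_run=4))
        elif r < 6:
            mix.append(ErrorSpec(DELETION, 1, "random"))
        elif r < 7:
            mix.append(ErrorSpec(INSERTION, 1, "in_homopolymer", min_run=3))
        elif r < 8:
            mix.append(ErrorSpec(INSERTION, 1, "random"))
        else:
            mix.append(ErrorSpec(SUBSTITUTION, 1, "random"))
    return mix


@dataclass(slots=True)
class SimulationSpec:
    """Full description of one synthetic world (see module docstring).

    Defaults describe the regime the polisher is built for: a 100 kb
    genome at 59% GC, ten references whose pairwise divergence sits at
    strain level (~95% identity when the per-reference substitution rate
    is 0.02), thirty-fold read coverage with ~1% read substitution error,
    and fifty well-separated injected draft errors.
    """

    seed: int
    genome_length: int = 100_000
    gc_content: float = 0.59
    contig_name: str = "contig_1"
    n_references: int = 10
    ref_sub_rate: float = 0.0
    ref_indel_rate: float = 0.0
    injected_errors: list[ErrorSpec] = field(default_factory=default_error_mix)
    read_depth: float = 30.0
    read_length: int = 2000
    read_sub_rate: float = 0.01
    read_hp_indel_rate: float = 0.01
    min_error_spacing: int = 50
    divergence_exclusion: int = 10
    edge_margin: int = 30
    coverage_gaps: tuple[tuple[int, int], ...] = ()
    n_secondary_references: int = 0

    def __post_init__(self) -> None:
        for name in ("ref_sub_rate", "ref_indel_rate", "read_sub_rate",
                     "read_hp_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.genome_length < 4 * self.edge_margin:
            raise ValueError("genome too short for the edge margin")


@dataclass(slots=True)
class _Edit:
    """One injected event in truth coordinates."""

    kind: str  # substitution | deletion (draft missing) | insertion (draft spurious)
    t: int  # truth coordinate (site, or insertion point before truth[t])
    seq: str  # substituted/missing/spurious bases


@dataclass(slots=True)
class World:
    spec: SimulationSpec
    truth: dict[str, str]
    draft: dict[str, str]
    references: dict[str, str]
    truth_errors: list[CandidateError]  # draft coordinates; applying them yields truth
    ref_pileup: Pileup
    read_pileup: Pileup
    secondary_pileup: Pileup | None = None

    def write(self, outdir) -> dict[str, Path]:
        """Serialize the whole world (FASTA + mpileup + truth TSV)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "truth": outdir / "truth.fasta",
            "draft": outdir / "draft.fasta",
            "references": outdir / "references.fasta",
            "truth_errors": outdir / "truth_errors.tsv",
            "ref_pileup": outdir / "references.mpileup",
            "read_pileup": outdir / "reads.mpileup",
        }
        write_fasta(self.truth, paths["truth"])
        write_fasta(self.draft, paths["draft"])
        write_fasta(self.references, paths["references"])
        write_error_table(self.truth_errors, paths["truth_errors"])
        write_mpileup(self.ref_pileup, self.draft, paths["ref_pileup"])
        write_mpileup(self.read_pileup, self.draft, paths["read_pileup"])
        if self.secondary_pileup is not None:
            paths["secondary_pileup"] = outdir / "secondary.mpileup"
            write_mpileup(self.secondary_pileup, self.draft,
                          paths["secondary_pileup"])
        return paths


# ---------------------------------------------------------------------------
# truth genome and error injection

def _random_genome(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=length, p=p))


def _find_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            if i - start >= min_len:
                runs.append((start, i))
            start = i
    return runs


def _canonical_indel_site(truth: str, t: int, seq: str, kind: str) -> int:
    """Slide a uniform-base indel to the right end of its run so every
    equivalent placement maps to one canonical coordinate."""
    if len(set(seq)) != 1:
        return t
    base = seq[0]
    end = t + len(seq) if kind == "deletion" else t
    while end < len(truth) and truth[end] == base:
        end += 1
        t += 1
    return t


def _choose_edits(rng: np.random.Generator, truth: str,
                  spec: SimulationSpec) -> list[_Edit]:
    chosen: list[_Edit] = []
    occupied: list[int] = []
    lo, hi = spec.edge_margin, len(truth) - spec.edge_margin
    runs_cache: dict[int, list[tuple[int, int]]] = {}

    def ok(t: int) -> bool:
        return lo <= t < hi and all(abs(t - o) >= spec.min_error_spacing
                                    for o in occupied)

    for es in spec.injected_errors:
        placed = None
        for _ in range(2000):
            if es.placement == "random":
                t = int(rng.integers(lo, hi))
                if es.error_type == SUBSTITUTION:
                    alt = _BASES[(_BASES.index(truth[t]) + int(rng.integers(1, 4))) % 4]
                    cand = _Edit("substitution", t, alt)
                elif es.error_type == DELETION:
                    seq = truth[t:t + es.length]
                    t2 = _canonical_indel_site(truth, t, seq, "deletion")
                    cand = _Edit("deletion", t2, truth[t2:t2 + es.length])
                else:
                    seq = "".join(rng.choice(list(_BASES), size=es.length))
                    t2 = _canonical_indel_site(truth, t, seq, "insertion")
                    cand = _Edit("insertion", t2, seq)
            elif es.placement == "after_kmer":
                if not es.kmer:
                    raise ValueError("after_kmer placement requires a kmer")
                hits = runs_cache.get(f"kmer:{es.kmer}")
                if hits is None:
                    hits = []
                    at = truth.find(es.kmer)
                    while at != -1:
                        hits.append((at, at + len(es.kmer)))
                        at = truth.find(es.kmer, at + 1)
                    runs_cache[f"kmer:{es.kmer}"] = hits
                if not hits:
                    raise ValueError(f"placement unsatisfiable: k-mer "
                                     f"{es.kmer!r} absent from the genome")
                _, kend = hits[int(rng.integers(len(hits)))]
                t = kend
                if es.error_type == SUBSTITUTION:
                    alt = _BASES[(_BASES.index(truth[t]) + int(rng.integers(1, 4))) % 4]
                    cand = _Edit("substitution", t, alt)
                elif es.error_type == DELETION:
                    cand = _Edit("deletion", t, truth[t:t + es.length])
                else:
                    base = truth[t]
                    cand = _Edit("insertion", t, base * es.length)
            else:  # in_homopolymer
                runs = runs_cache.get(f"run:{es.min_run}")
                if runs is None:
                    runs = runs_cache[f"run:{es.min_run}"] = _find_runs(truth, es.min_run)
                if not runs:
                    raise ValueError(f"placement unsatisfiable: no homopolymer "
                                     f">= {es.min_run} nt in the genome")
                rstart, rend = runs[int(rng.integers(len(runs)))]
                base = truth[rstart]
                if es.error_type == SUBSTITUTION:
                    t = rend  # just after the run
                    if t >= len(truth):
                        continue
                    alt = _BASES[(_BASES.index(truth[t]) + int(rng.integers(1, 4))) % 4]
                    cand = _Edit("substitution", t, alt)
                elif es.error_type == DELETION:
                    t = rend - es.length  # delete the run's last bases
                    if t < rstart:
                        continue
                    cand = _Edit("deletion", t, base * es.length)
                else:
                    t = rend  # extra copies appended to the run
                    cand = _Edit("insertion", t, base * es.length)
            if es.error_type != SUBSTITUTION and cand.seq == "":
                continue
            if ok(cand.t):
                placed = cand
                break
        if placed is None:
            raise ValueError(
                f"could not place error {es} with spacing "
                f">= {spec.min_error_spacing} nt; reduce the error count or "
                "spacing"
            )
        chosen.append(placed)
        occupied.append(placed.t)
    chosen.sort(key=lambda e: e.t)
    return chosen


def inject_errors(truth: str, edits: list[_Edit], contig: str,
                  ) -> tuple[str, list[CandidateError], np.ndarray, np.ndarray]:
    """Apply injected edits to the truth, producing the draft, the
    ground-truth error list in draft coordinates, and both coordinate
    maps (truth->draft and draft->truth; -1 marks positions with no
    counterpart)."""
    parts: list[str] = []
    errors: list[CandidateError] = []
    t2d = np.full(len(truth), -1, dtype=np.int64)
    d2t: list[int] = []
    prev = 0
    d = 0
    for ed in edits:
        for t in range(prev, ed.t):
            t2d[t] = d
            d2t.append(t)
            d += 1
        parts.append(truth[prev:ed.t])
        if ed.kind == "substitution":
            parts.append(ed.seq)
            errors.append(CandidateError(
                contig=contig, position=d, error_type=SUBSTITUTION,
                length=1, draft_seq=ed.seq, correction_seq=truth[ed.t]))
            t2d[ed.t] = d
            d2t.append(ed.t)
            d += 1
            prev = ed.t + 1
        elif ed.kind == "deletion":
            errors.append(CandidateError(
                contig=contig, position=d - 1, error_type=DELETION,
                length=len(ed.seq), draft_seq="", correction_seq=ed.seq))
            prev = ed.t + len(ed.seq)
        else:  # draft gains spurious bases before truth[ed.t]
            parts.append(ed.seq)
            errors.append(CandidateError(
                contig=contig, position=d, error_type=INSERTION,
                length=len(ed.seq), draft_seq=ed.seq, correction_seq=""))
            for _ in ed.seq:
                d2t.append(-1)
                d += 1
            prev = ed.t
    for t in range(prev, len(truth)):
        t2d[t] = d
        d2t.append(t)
        d += 1
    parts.append(truth[prev:])
    return "".join(parts), errors, t2d, np.array(d2t, dtype=np.int64)


# ---------------------------------------------------------------------------
# exact pileups from known edits

@dataclass(slots=True)
class _SourceEvents:
    """Overlay of one aligned source's private differences vs the draft."""

    mismatch: dict[int, str] = field(default_factory=dict)
    gaps: set[int] = field(default_factory=set)
    ins_anchor: dict[int, str] = field(default_factory=dict)
    del_anchor: dict[int, str] = field(default_factory=dict)


@dataclass(slots=True)
class _InjectedTemplate:
    """Events every truth-carrying source shows against the draft."""

    mismatch: dict[int, str] = field(default_factory=dict)
    gaps: set[int] = field(default_factory=set)
    ins_anchor: dict[int, str] = field(default_factory=dict)
    del_anchor: dict[int, str] = field(default_factory=dict)
    zones: list[tuple[int, int]] = field(default_factory=list)  # draft coords


def _injected_template(errors: list[CandidateError], margin: int,
                       draft_len: int) -> _InjectedTemplate:
    tpl = _InjectedTemplate()
    for e in errors:
        if e.error_type == SUBSTITUTION:
            tpl.mismatch[e.position] = e.correction_seq
            zone = (e.position, e.position + 1)
        elif e.error_type == INSERTION:
            tpl.gaps.update(range(e.position, e.position + e.length))
            tpl.del_anchor[e.position - 1] = e.draft_seq
            zone = (e.position - 1, e.position + e.length)
        else:
            tpl.ins_anchor[e.position] = e.correction_seq
            zone = (e.position, e.position + 1)
        tpl.zones.append((max(0, zone[0] - margin),
                          min(draft_len, zone[1] + margin)))
    return tpl


def _zone_mask(zones: list[tuple[int, int]], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in zones:
        mask[s:e] = True
    return mask


def _sample_source_divergence(rng, truth: str, t2d: np.ndarray,
                              allowed_truth: np.ndarray, sub_rate: float,
                              indel_rate: float,
                              ) -> tuple[_SourceEvents, list[tuple]]:
    """Private variants of one reference, in draft coordinates, plus the
    truth-coordinate edit list used to build its FASTA sequence."""
    ev = _SourceEvents()
    truth_edits: list[tuple] = []  # (t, kind, seq)
    L = len(truth)
    used = np.zeros(L, dtype=bool)
    if sub_rate > 0:
        for t in np.flatnonzero(rng.random(L) < sub_rate):
            t = int(t)
            if t < 1 or not allowed_truth[t] or used[max(0, t - 4):t + 5].any():
                continue
            alt = _BASES[(_BASES.index(truth[t]) + int(rng.integers(1, 4))) % 4]
            ev.mismatch[int(t2d[t])] = alt
            truth_edits.append((t, "sub", alt))
            used[t] = True
    if indel_rate > 0:
        for t in np.flatnonzero(rng.random(L) < indel_rate):
            t = int(t)
            length = 1 + int(rng.random() < 0.3)
            if t < 2 or t + length + 1 >= L \
                    or not allowed_truth[t - 1:t + length + 1].all() \
                    or used[max(0, t - 6):t + length + 6].any() \
                    or t2d[t] < 2:
                continue
            if rng.random() < 0.5:  # reference lacks truth bases
                d = int(t2d[t])
                ev.del_anchor[d - 1] = truth[t:t + length]
                ev.gaps.update(range(d, d + length))
                truth_edits.append((t, "del", truth[t:t + length]))
            else:  # reference carries extra bases before truth[t]
                seq = "".join(rng.choice(list(_BASES), size=length))
                ev.ins_anchor[int(t2d[t]) - 1] = seq
                truth_edits.append((t, "ins", seq))
            used[t:t + length] = True
    return ev, truth_edits


def _apply_truth_edits(truth: str, edits: list[tuple]) -> str:
    parts = []
    prev = 0
    for t, kind, seq in sorted(edits):
        parts.append(truth[prev:t])
        if kind == "sub":
            parts.append(seq)
            prev = t + 1
        elif kind == "del":
            prev = t + len(seq)
        else:
            parts.append(seq)
            prev = t
    parts.append(truth[prev:])
    return "".join(parts)


def _empty_pileup(contig: str, draft_seq: str) -> Pileup:
    pileup = Pileup()
    pileup.contigs[contig] = [
        PileupColumn(contig=contig, pos=i, draft_base=b)
        for i, b in enumerate(draft_seq)
    ]
    return pileup


def _add_source(pileup: Pileup, contig: str, segment: tuple[int, int],
                tpl: _InjectedTemplate, ev: _SourceEvents) -> int:
    """Lay one aligned source over the pileup and return its id."""
    src = len(pileup.source_starts)
    pileup.source_starts.append(segment[0])
    cols = pileup.contigs[contig]
    last = segment[1] - 1
    for d in range(*segment):
        if d in tpl.gaps or d in ev.gaps:
            kind, base = "gap", ""
        elif d in tpl.mismatch:
            kind, base = "mismatch", tpl.mismatch[d]
        elif d in ev.mismatch:
            kind, base = "mismatch", ev.mismatch[d]
        else:
            kind, base = "match", ""
        ins = tpl.ins_anchor.get(d) or ev.ins_anchor.get(d) or ""
        dele = tpl.del_anchor.get(d) or ev.del_anchor.get(d) or ""
        if d == last:
            dele = ""  # a deletion cannot extend past the segment end
        cols[d].observations.append(Observation(
            source=src, kind=kind, base=base, insertion=ins, deletion=dele))
    return src


def _segments(length: int, gaps: tuple[tuple[int, int], ...]) -> list[tuple[int, int]]:
    segs = []
    prev = 0
    for s, e in sorted(gaps):
        if s > prev:
            segs.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        segs.append((prev, length))
    return segs


# ---------------------------------------------------------------------------
# reads

def _simulate_reads(rng, draft_seq: str, contig: str, tpl: _InjectedTemplate,
                    spec: SimulationSpec) -> Pileup:
    L = len(draft_seq)
    rl = spec.read_length
    n_reads = math.ceil(spec.read_depth * (L + rl) / rl)
    starts = np.sort(rng.integers(-(rl - 1), L - 1, size=n_reads))
    zone_mask = _zone_mask(tpl.zones, L)
    hp_runs = [(s, e) for s, e in _find_runs(draft_seq, 2)
               if not zone_mask[s:e].any()]
    run_starts = np.array([s for s, _ in hp_runs], dtype=np.int64)
    pileup = _empty_pileup(contig, draft_seq)

    for raw_start in starts:
        s, e = max(0, int(raw_start)), min(L, int(raw_start) + rl)
        if e - s < 50:
            continue
        ev = _SourceEvents()
        # homopolymer-length miscalls, escalating with run length
        lo = int(np.searchsorted(run_starts, s + 1))
        hi = int(np.searchsorted(run_starts, e - 3))
        for ri in range(lo, hi):
            rs, re_ = hp_runs[ri]
            if re_ >= e:
                continue
            p = min(0.4, spec.read_hp_indel_rate * (re_ - rs - 1))
            if p <= 0 or rng.random() >= p:
                continue
            base = draft_seq[rs]
            if rng.random() < 0.5 and re_ - rs >= 2:
                ev.del_anchor[re_ - 2] = draft_seq[re_ - 1]
                ev.gaps.add(re_ - 1)
            else:
                ev.ins_anchor[re_ - 1] = base
        # per-base substitution miscalls at plain columns
        if spec.read_sub_rate > 0:
            for off in np.flatnonzero(rng.random(e - s) < spec.read_sub_rate):
                d = s + int(off)
                if zone_mask[d] or d in ev.gaps or d in ev.mismatch:
                    continue
                alt = _BASES[(_BASES.index(draft_seq[d]) + int(rng.integers(1, 4))) % 4]
                ev.mismatch[d] = alt
        _add_source(pileup, contig, (s, e), tpl, ev)
    return pileup


# ---------------------------------------------------------------------------
# the world

def simulate_world(spec: SimulationSpec) -> World:
    """Build a complete seeded world (see module docstring).

    The generated draft, ground-truth error list and both pileups are
    mutually consistent by construction: applying the truth list to the
    draft reproduces the truth genome (asserted here), and every pileup
    event derives from a recorded edit.
    """
    rng = np.random.default_rng(spec.seed)
    contig = spec.contig_name
    truth_seq = _random_genome(rng, spec.genome_length, spec.gc_content)
    edits = _choose_edits(rng, truth_seq, spec)
    draft_seq, truth_errors, t2d, _d2t = inject_errors(truth_seq, edits, contig)

    reconstructed = apply_errors({contig: draft_seq}, truth_errors)[contig]
    if reconstructed != truth_seq:
        raise AssertionError("internal consistency failure: ground-truth "
                             "error list does not reproduce the truth genome")

    tpl = _injected_template(truth_errors, spec.divergence_exclusion,
                             len(draft_seq))
    # exclusion zones in truth coordinates: forbid divergence wherever a
    # draft zone maps back, plus deleted truth bases and their flanks
    allowed_truth = np.ones(len(truth_seq), dtype=bool)
    allowed_truth[t2d < 0] = False  # truth bases absent from the draft
    zone_mask_draft = _zone_mask(tpl.zones, len(draft_seq))
    d2t_ok = _d2t >= 0
    for d in np.flatnonzero(zone_mask_draft):
        if d2t_ok[d]:
            allowed_truth[_d2t[d]] = False
    for ed in edits:
        if ed.kind == "deletion":
            lo = max(0, ed.t - spec.divergence_exclusion)
            hi = min(len(truth_seq), ed.t + len(ed.seq) + spec.divergence_exclusion)
            allowed_truth[lo:hi] = False

    ref_pileup = _empty_pileup(contig, draft_seq)
    references: dict[str, str] = {}
    segments = _segments(len(draft_seq), spec.coverage_gaps)
    for i in range(spec.n_references):
        ev, truth_edits = _sample_source_divergence(
            rng, truth_seq, t2d, allowed_truth, spec.ref_sub_rate,
            spec.ref_indel_rate)
        references[f"ref_{i + 1}"] = _apply_truth_edits(truth_seq, truth_edits)
        for seg in segments:
            _add_source(ref_pileup, contig, seg, tpl, ev)

    secondary = None
    if spec.n_secondary_references > 0:
        secondary = _empty_pileup(contig, draft_seq)
        for i in range(spec.n_secondary_references):
            ev, truth_edits = _sample_source_divergence(
                rng, truth_seq, t2d, allowed_truth, spec.ref_sub_rate,
                spec.ref_indel_rate)
            references[f"ref2_{i + 1}"] = _apply_truth_edits(truth_seq, truth_edits)
            _add_source(secondary, contig, (0, len(draft_seq)), tpl, ev)

    read_pileup = _simulate_reads(rng, draft_seq, contig, tpl, spec)

    return World(spec=spec, truth={contig: truth_seq},
                 draft={contig: draft_seq}, references=references,
                 truth_errors=truth_errors, ref_pileup=ref_pileup,
                 read_pileup=read_pileup, secondary_pileup=secondary)


# ---------------------------------------------------------------------------
# helpers for stress tests and independent cross-checks

def offset_indels_within_runs(errors: list[CandidateError],
                              draft: dict[str, str],
                              rng: np.random.Generator,
                              max_offset: int = 3) -> list[CandidateError]:
    """Mis-position indel candidates by up to ``max_offset`` nt within
    their homopolymer run (substitutions pass through untouched); used to
    exercise read-based repositioning against a known true site."""
    out: list[CandidateError] = []
    for e in errors:
        seq = draft[e.contig]
        if e.error_type == INSERTION:
            run = run_at(seq, e.position)
            lo = max(run.start, e.position - max_offset)
            hi = min(run.end - e.length, e.position + max_offset)
            choices = [p for p in range(lo, hi + 1) if p != e.position]
            if not choices:
                out.append(e)
                continue
            p = int(choices[int(rng.integers(len(choices)))])
            out.append(replace(e, position=p, draft_seq=seq[p:p + e.length]))
        elif e.error_type == DELETION:
            run = insertion_run(seq, e.position, e.correction_seq)
            if run is None:
                out.append(e)
                continue
            lo = max(run.start - 1, e.position - max_offset, 0)
            hi = min(run.end - 1, e.position + max_offset)
            choices = [p for p in range(lo, hi + 1) if p != e.position]
            if not choices:
                out.append(e)
                continue
            out.append(replace(e, position=int(choices[int(rng.integers(len(choices)))])))
        else:
            out.append(e)
    return out


def pileup_from_alignment(references: dict[str, str],
                          draft: dict[str, str]) -> Pileup:
    """Align whole reference sequences to the draft with edlib and convert
    each global alignment into pileup events.

    This is an independent route to a reference pileup (a real aligner,
    not the edit-composition bookkeeping above); used to re-check a
    corrected assembly against its references.
    """
    import edlib

    assert len(draft) == 1, "single-contig drafts only"
    (contig, draft_seq), = draft.items()
    pileup = _empty_pileup(contig, draft_seq)
    tpl = _InjectedTemplate()  # no shared events
    for name in references:
        ref = references[name]
        result = edlib.align(ref, draft_seq, mode="NW", task="path")
        ev = _SourceEvents()
        d = 0  # draft cursor
        q = 0  # reference cursor
        for count, op in _parse_cigar(result["cigar"]):
            if op in "=M":
                for k in range(count):
                    if ref[q + k] != draft_seq[d + k]:
                        ev.mismatch[d + k] = ref[q + k]
                d += count
                q += count
            elif op == "X":
                for k in range(count):
                    ev.mismatch[d + k] = ref[q + k]
                d += count
                q += count
            elif op == "I":  # consumes reference only: extra ref bases
                ev.ins_anchor[d - 1] = ref[q:q + count]
                q += count
            elif op == "D":  # consumes draft only: ref lacks draft bases
                ev.del_anchor[d - 1] = draft_seq[d:d + count]
                ev.gaps.update(range(d, d + count))
                d += count
            else:
                raise ValueError(f"unexpected CIGAR op {op!r}")
        _add_source(pileup, contig, (0, len(draft_seq)), tpl, ev)
    return pileup


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""
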