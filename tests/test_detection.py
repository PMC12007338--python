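"""Candidate detection: ADPs, window schedule, scoring and the full scan."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import BASES, brute_positional_adp, brute_regional_adp, random_columns
from refpolish.config import PolishConfig
from refpolish.detection import (
    coverage_gate,
    detect,
    positional_adp,
    regional_adp,
    score_region,
    strategies_enabled,
    window_schedule,
)
from refpolish.model import Observation, PileupColumn
from refpolish.simulate import SimulationSpec, default_error_mix, simulate_world


def _column(draft_base="G", observations=()):
    col = PileupColumn(contig="c", pos=0, draft_base=draft_base)
    col.observations = list(observations)
    return col


def test_positional_adp_all_references_mismatch():
    # a draft G aligning with a conserved A in every reference
    col = _column("G", [Observation(source=i, kind="mismatch", base="A")
                        for i in range(10)])
    adp, alts = positional_adp(col, "substitution")
    assert adp == 1.0
    assert alts == {"A": 10}


def test_positional_adp_insertion_error_fraction():
    obs = [Observation(source=i, kind="match", deletion="T") for i in range(8)]
    obs += [Observation(source=i, kind="match") for i in range(8, 10)]
    adp, by_len = positional_adp(_column("G", obs), "insertion")
    assert adp == 0.8
    assert by_len == {1: 8}


def test_positional_adp_ignores_long_indels():
    # 3 nt events are strain variants, never candidate errors
    obs = [Observation(source=i, kind="match", insertion="AGT")
           for i in range(10)]
    adp, details = positional_adp(_column("G", obs), "deletion")
    assert adp == 0.0 and details == {}


def test_positional_adp_requires_coverage():
    with pytest.raises(ValueError, match="zero depth"):
        positional_adp(_column("G", []), "substitution")


@pytest.mark.parametrize("depth,expected", [(5, True), (4, False), (0, False)])
def test_coverage_gate_inclusive(depth, expected):
    col = _column("G", [Observation(source=i) for i in range(depth)])
    assert coverage_gate(col, 5) is expected


def test_window_schedule():
    cfg = PolishConfig()
    draft = "A" * 90 + "TTTTT" + "A" * 105  # run at positions 90..95
    assert window_schedule(1, draft, 100, cfg) == (100, 101)
    assert window_schedule(2, draft, 92, cfg) == (90, 95)  # homopolymer extent
    assert window_schedule(3, draft, 100, cfg) == (95, 106)  # 11 nt centred
    assert window_schedule(4, draft, 100, cfg) == (90, 111)  # +5 nt per side
    assert window_schedule(3, draft, 2, cfg) == (0, 8)  # truncated at start
    with pytest.raises(ValueError, match="pass"):
        window_schedule(7, draft, 100, cfg)


def test_strategies_on_every_second_elective_pass():
    cfg = PolishConfig()
    assert [p for p in range(1, 7) if strategies_enabled(p, cfg)] == [4, 6]


def test_regional_adp_counts_each_source_once():
    # one reference with three deletions in the window contributes 1/10
    cols = []
    for pos in range(7):
        col = PileupColumn(contig="c", pos=pos, draft_base="A")
        for src in range(10):
            dele = "A" if src == 0 and pos in (1, 3, 5) else ""
            col.observations.append(Observation(source=src, deletion=dele))
        cols.append(col)
    adp, contributing = regional_adp(cols, (0, 7), "insertion",
                                     PolishConfig(), trigger_pos=3)
    assert adp == pytest.approx(0.1)
    assert contributing == {0}


def test_regional_adp_saturates_at_one():
    cols = []
    for pos in range(5):
        col = PileupColumn(contig="c", pos=pos, draft_base="A")
        for src in range(7):
            ins = "T" if pos == src % 5 else ""
            col.observations.append(Observation(source=src, insertion=ins))
        cols.append(col)
    adp, _ = regional_adp(cols, (0, 5), "deletion", PolishConfig(), 2)
    assert adp == 1.0


def test_adp_oracle_equivalence_random_fixtures():
    """Positional and regional ADP match an independent brute-force
    recount over randomized columns and windows."""
    rng = np.random.default_rng(2024)
    cfg = PolishConfig()
    for trial in range(60):
        n_sources = int(rng.integers(7, 16))
        n_cols = int(rng.integers(5, 25))
        _, cols = random_columns(rng, n_cols, n_sources)
        for col in cols:
            for etype in ("substitution", "insertion", "deletion"):
                assert positional_adp(col, etype)[0] == \
                    brute_positional_adp(col, etype)
        for _ in range(5):
            trigger = int(rng.integers(n_cols))
            a = int(rng.integers(n_cols))
            window = (min(a, trigger), max(a, trigger) + 1)
            for etype in ("substitution", "insertion", "deletion"):
                assert regional_adp(cols, window, etype, cfg, trigger)[0] == \
                    brute_regional_adp(cols, window, etype, trigger)


# ---------------------------------------------------------------------------
# scoring

def _scored_world(draft, site_events, n_sources=10):
    """Columns over ``draft`` with per-position events: {pos: (etype_evt, n)}
    where etype_evt is ('mismatch', base) / ('ins', seq) / ('del', seq)."""
    cols = []
    for pos in range(len(draft)):
        col = PileupColumn(contig="c", pos=pos, draft_base=draft[pos])
        kind, payload, n = site_events.get(pos, ("none", "", 0))
        for src in range(n_sources):
            if src < n and kind == "mismatch":
                col.observations.append(
                    Observation(source=src, kind="mismatch", base=payload))
            elif src < n and kind == "ins":
                col.observations.append(Observation(source=src, insertion=payload))
            elif src < n and kind == "del":
                col.observations.append(Observation(source=src, deletion=payload))
            else:
                col.observations.append(Observation(source=src))
        cols.append(col)
    return cols


def test_score_is_frequency_times_run_length():
    # deletion error: 6/10 refs insert an extra A against an AAAAA run
    draft = "GCTAAAAAGCT"
    cols = _scored_world(draft, {7: ("ins", "A", 6)})
    cand = score_region(cols, draft, "c", (2, 9), "deletion", PolishConfig(), 1)
    assert cand.score == pytest.approx(0.6 * 5)
    assert cand.position == 7  # canonical: last base of the run
    assert cand.correction_seq == "A"


def test_score_halved_when_correction_splits_run():
    # inserting a G inside an AAAAA run breaks it: penalized by half
    draft = "GCTAAAAAGCT"
    cols = _scored_world(draft, {5: ("ins", "G", 6)})
    cand = score_region(cols, draft, "c", (2, 9), "deletion", PolishConfig(), 1)
    assert cand.score == pytest.approx(0.6 * 1 * 0.5)


def test_score_tie_breaks_leftmost():
    draft = "ACGTACGTACGT"
    cols = _scored_world(draft, {3: ("mismatch", "A", 6), 8: ("mismatch", "C", 6)})
    cand = score_region(cols, draft, "c", (0, 12), "substitution", PolishConfig())
    assert cand.position == 3


def test_score_merges_same_run_same_type_sites():
    # two deletion signals on one run, disjoint reference sets: merged
    # support covers both (0.3 + 0.3) x run length 5
    draft = "GCTTTTTGCA"
    cols = []
    for pos in range(len(draft)):
        col = PileupColumn(contig="c", pos=pos, draft_base=draft[pos])
        for src in range(10):
            ins = "T" if (pos == 4 and src < 3) or (pos == 6 and 3 <= src < 6) else ""
            col.observations.append(Observation(source=src, insertion=ins))
        cols.append(col)
    cand = score_region(cols, draft, "c", (2, 9), "deletion", PolishConfig(), 1)
    assert cand.score == pytest.approx(0.6 * 5)


# ---------------------------------------------------------------------------
# the full scan

def test_detect_recovers_single_injected_deletion():
    world = simulate_world(SimulationSpec(
        seed=21, genome_length=4000, read_depth=0.0,
        injected_errors=[__import__("refpolish").ErrorSpec(
            "deletion", 1, "in_homopolymer", min_run=4)]))
    truth = world.truth_errors[0]
    found = detect(world.ref_pileup, world.draft, PolishConfig())
    assert len(found) == 1
    cand = found[0]
    assert (cand.error_type, cand.position, cand.correction_seq) == \
        ("deletion", truth.position, truth.correction_seq)
    assert cand.reference_adp == 1.0 and cand.pass_found == 1


def test_detect_respects_coverage_gate(zero_world):
    high_gate = PolishConfig(min_ref_coverage=zero_world.spec.n_references + 1)
    assert detect(zero_world.ref_pileup, zero_world.draft, high_gate) == []


def test_detect_zero_divergence_recovery(zero_world):
    """Identical references + injected errors: 100% sensitivity, zero
    candidates anywhere else."""
    found = detect(zero_world.ref_pileup, zero_world.draft, PolishConfig())
    truth = {(e.error_type, e.position) for e in zero_world.truth_errors}
    got = {(e.error_type, e.position) for e in found}
    assert got == truth


def test_detect_full_consensus_at_default_threshold(divergent_world):
    """At threshold 0.99 with <= 15 references every emitted candidate is
    backed by 100% of covering references in its window."""
    found = detect(divergent_world.ref_pileup, divergent_world.draft,
                   PolishConfig())
    assert found, "expected candidates on the divergent world"
    for cand in found:
        assert cand.regional_adp == 1.0


def test_detect_monotone_in_error_threshold(divergent_world):
    counts = []
    for thr in (0.5, 0.75, 0.99):
        cfg = PolishConfig(error_threshold=thr)
        counts.append(len(detect(divergent_world.ref_pileup,
                                 divergent_world.draft, cfg)))
    assert counts == sorted(counts, reverse=True)


def test_detect_candidate_bounds(divergent_world):
    cfg = PolishConfig(error_threshold=0.5)
    for cand in detect(divergent_world.ref_pileup, divergent_world.draft, cfg):
        if cand.error_type != "substitution":
            assert cand.length <= cfg.max_indel_len
        assert 0.0 <= cand.reference_adp <= 1.0
        assert cfg.error_threshold <= cand.regional_adp <= 1.0


def test_detect_deterministic(zero_world):
    a = detect(zero_world.ref_pileup, zero_world.draft, PolishConfig())
    b = detect(zero_world.ref_pileup, zero_world.draft, PolishConfig())
    assert a == b


def test_detect_uses_secondary_pileup_in_low_coverage_regions():
    """An injected error inside a primary-coverage gap is found only when
    the secondary reference set is supplied."""
    base = dict(seed=31, genome_length=8000,
                injected_errors=default_error_mix(10), read_depth=0.0,
                n_secondary_references=8)
    probe = simulate_world(SimulationSpec(**base))
    target = probe.truth_errors[3]
    gap = (max(0, target.position - 150), target.position + 150)
    world = simulate_world(SimulationSpec(**base, coverage_gaps=(gap,)))
    assert [(e.error_type, e.position) for e in world.truth_errors] == \
        [(e.error_type, e.position) for e in probe.truth_errors]

    without = detect(world.ref_pileup, world.draft, PolishConfig())
    with_sec = detect(world.ref_pileup, world.draft, PolishConfig(),
                      world.secondary_pileup)
    key = (target.error_type, target.position)
    assert key not in {(e.error_type, e.position) for e in without}
    assert key in {(e.error_type, e.position) for e in with_sec}
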