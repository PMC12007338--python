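"""Self-consistency of the synthetic-world generator."""

from __future__ import annotations

import numpy as np
import pytest

from refpolish.correction import apply_errors
from refpolish.simulate import (
    ErrorSpec,
    SimulationSpec,
    default_error_mix,
    pileup_from_alignment,
    simulate_world,
)


def _small_spec(**kw):
    base = dict(seed=51, genome_length=6000,
                injected_errors=default_error_mix(10), read_depth=12.0,
                read_length=600)
    base.update(kw)
    return SimulationSpec(**base)


def test_same_seed_same_bytes(tmp_path):
    a = simulate_world(_small_spec())
    b = simulate_world(_small_spec())
    pa = a.write(tmp_path / "a")
    pb = b.write(tmp_path / "b")
    for name in pa:
        assert pa[name].read_bytes() == pb[name].read_bytes(), name


def test_truth_error_list_reproduces_truth():
    world = simulate_world(_small_spec())
    assert apply_errors(world.draft, world.truth_errors) == world.truth


def test_injected_errors_change_draft_as_declared():
    world = simulate_world(_small_spec(seed=52))
    (contig, draft), = world.draft.items()
    truth = world.truth[contig]
    gain = sum(e.length for e in world.truth_errors if e.error_type == "deletion")
    loss = sum(e.length for e in world.truth_errors if e.error_type == "insertion")
    assert len(draft) == len(truth) - gain + loss
    for e in world.truth_errors:
        if e.error_type == "insertion":
            assert draft[e.position:e.position + e.length] == e.draft_seq
        elif e.error_type == "substitution":
            assert draft[e.position] == e.draft_seq != e.correction_seq


def test_divergent_refs_never_reach_consensus_off_target():
    """With per-reference independent variants, no non-injected column has
    every covering reference disagreeing with the draft."""
    world = simulate_world(_small_spec(seed=53, ref_sub_rate=0.03,
                                       ref_indel_rate=0.004))
    injected = set()
    for e in world.truth_errors:
        injected.update(range(max(0, e.position - 1), e.position + e.length + 1))
    (contig, cols), = world.ref_pileup.contigs.items()
    for col in cols:
        if col.pos in injected or col.depth == 0:
            continue
        different = sum(bool(o.kind != "match" or o.insertion or o.deletion)
                        for o in col.observations)
        assert different < col.depth


def test_read_support_for_truth_at_injected_sites():
    """Reads are drawn from the truth: at every injected error site the
    fraction of reads supporting the true state is ~1 (within binomial
    noise of the read error model)."""
    world = simulate_world(_small_spec(seed=54, read_depth=30.0))
    (contig, cols), = world.read_pileup.contigs.items()
    for e in world.truth_errors:
        col = cols[e.position]
        if e.error_type == "substitution":
            support = sum(o.kind == "mismatch" and o.base == e.correction_seq
                          for o in col.observations)
        elif e.error_type == "insertion":
            anchor = cols[e.position - 1]
            support = sum(o.deletion == e.draft_seq
                          for o in anchor.observations)
            col = anchor
        else:
            support = sum(o.insertion == e.correction_seq
                          for o in col.observations)
        assert col.depth > 0
        assert support / col.depth >= 0.9  # read errors spare injected zones


def test_unsatisfiable_placement_raises():
    with pytest.raises(ValueError, match="unsatisfiable"):
        simulate_world(_small_spec(
            injected_errors=[ErrorSpec("deletion", 1, "in_homopolymer",
                                       min_run=40)]))


def test_overcrowded_spec_raises():
    with pytest.raises(ValueError, match="spacing"):
        simulate_world(_small_spec(
            genome_length=4000,
            injected_errors=default_error_mix(200)))


def test_alignment_pileup_agrees_on_identical_sequences():
    """The edlib-alignment route reports all-match pileups when references
    equal the draft (independent cross-check of the event bookkeeping)."""
    world = simulate_world(_small_spec(seed=55, injected_errors=[]))
    assert world.draft == world.truth
    pile = pileup_from_alignment({"r1": world.truth["contig_1"]}, world.draft)
    for col in pile.contigs["contig_1"]:
        assert [o.kind for o in col.observations] == ["match"]
        assert all(not o.insertion and not o.deletion for o in col.observations)
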