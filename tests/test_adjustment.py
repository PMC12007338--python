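"""Read-based adjustment: profiles, confirmation, relocation, splitting."""

from __future__ import annotations

import numpy as np
import pytest

from refpolish.adjustment import (
    adjust_all,
    adjust_indel,
    confirm_substitution,
    read_adp_profile,
)
from refpolish.config import PolishConfig
from refpolish.model import CandidateError, Observation, Pileup, PileupColumn
from refpolish.simulate import (
    SimulationSpec,
    default_error_mix,
    offset_indels_within_runs,
    simulate_world,
)


def _columns(draft, per_read_events, n_reads=10):
    """Read columns over ``draft``: per_read_events[read] is a dict
    pos -> ('ins'|'del'|'mismatch', payload)."""
    cols = []
    for pos in range(len(draft)):
        col = PileupColumn(contig="c", pos=pos, draft_base=draft[pos])
        for read in range(n_reads):
            kind, base, ins, dele = "match", "", "", ""
            evt = per_read_events.get(read, {}).get(pos)
            if evt:
                if evt[0] == "ins":
                    ins = evt[1]
                elif evt[0] == "del":
                    dele = evt[1]
                else:
                    kind, base = "mismatch", evt[1]
            col.observations.append(Observation(
                source=read, kind=kind, base=base, insertion=ins, deletion=dele))
        cols.append(col)
    return cols


def _as_pileup(cols):
    pile = Pileup()
    pile.contigs["c"] = cols
    pile.source_starts = [0] * (max(o.source for c in cols
                                    for o in c.observations) + 1)
    return pile


def test_profile_groups_run_evidence_into_one_site():
    # insertion evidence scattered along an AAAAA run: one representative
    # site at the canonical run-end anchor, ADP = pooled distinct reads
    draft = "GCTAAAAAGCT"
    events = {r: {3 + r % 5: ("ins", "A")} for r in range(3)}
    profile = read_adp_profile(_columns(draft, events), draft, (0, 11),
                               "deletion", 1)
    assert len(profile) == 1
    site = next(iter(profile.values()))
    assert site.position == 7 and site.adp == pytest.approx(0.3)


def test_profile_keeps_run_breaking_event_separate():
    draft = "GCTAAAAAGCT"
    events = {0: {5: ("ins", "A")}, 1: {5: ("ins", "G")}}
    profile = read_adp_profile(_columns(draft, events), draft, (0, 11),
                               "deletion", 1)
    positions = sorted(s.position for s in profile.values())
    assert positions == [5, 7]  # breaker at its own anchor, run at canon end


def test_profile_matches_per_read_recount():
    rng = np.random.default_rng(9)
    draft = "".join(rng.choice(list("ACGT"), size=40))
    events = {}
    for read in range(12):
        if rng.random() < 0.7:
            pos = int(rng.integers(1, 39))
            events.setdefault(read, {})[pos] = ("ins", str(rng.choice(list("ACGT"))))
    cols = _columns(draft, events, n_reads=12)
    profile = read_adp_profile(cols, draft, (0, 40), "deletion", 1)
    total_support = sum(s.support for s in profile.values())
    brute = len({r for r, evs in events.items()
                 for _, e in evs.items() if e[0] == "ins"})
    assert total_support == brute  # each read counted once per group


def test_indel_confirmed_at_threshold_boundary():
    # read ADP exactly at the 25% threshold confirms without searching
    draft = "GCGCTAGCTAGC"
    events = {r: {4: ("ins", "T")} for r in range(3)}  # 3/12 reads = 0.25
    pile = _as_pileup(_columns(draft, events, n_reads=12))
    cand = CandidateError("c", 4, "deletion", 1, "", "T",
                          reference_adp=1.0, regional_adp=1.0)
    out = adjust_indel(cand, pile, PolishConfig(), {"c": draft})
    assert [(e.status, e.position, e.read_adp) for e in out] == \
        [("confirmed", 4, 0.25)]


def test_indel_relocates_to_best_supported_site():
    draft = "GCGCTAGCTAGCGT"
    events = {r: {4: ("del", "A")} for r in range(6)}  # reads delete pos 5
    pile = _as_pileup(_columns(draft, events, n_reads=10))
    cand = CandidateError("c", 8, "insertion", 1, "T", "",
                          reference_adp=1.0, regional_adp=1.0)
    out = adjust_indel(cand, pile, PolishConfig(), {"c": draft})
    assert len(out) == 1
    assert out[0].status == "adjusted"
    assert out[0].position == 5 and out[0].original_position == 8
    assert out[0].draft_seq == draft[5]


def test_unsupported_indel_is_retained_never_dropped():
    draft = "GCGCTAGCTAGC"
    pile = _as_pileup(_columns(draft, {}, n_reads=10))
    cand = CandidateError("c", 6, "deletion", 1, "", "T")
    out = adjust_indel(cand, pile, PolishConfig(), {"c": draft})
    assert [(e.status, e.position) for e in out] == \
        [("retained_unsupported", 6)]


def test_two_nt_indel_splits_into_two_supported_singles():
    draft = "GCATTTTCGGGAC"
    # reads support single deletions in the T run and in the G run, but no
    # 2 nt deletion anywhere
    events = {r: {5: ("ins", "T")} for r in range(4)}
    for r in range(4, 8):
        events[r] = {9: ("ins", "G")}
    pile = _as_pileup(_columns(draft, events, n_reads=10))
    cand = CandidateError("c", 6, "deletion", 2, "", "TT")
    out = adjust_indel(cand, pile, PolishConfig(), {"c": draft})
    assert [e.status for e in out] == ["split", "split"]
    assert [e.length for e in out] == [1, 1]
    assert sorted(e.correction_seq for e in out) == ["G", "T"]
    assert all(e.original_position == 6 for e in out)


def test_substitution_confirmed_with_best_alternative():
    draft = "GCGCTGGCTAGC"
    events = {r: {5: ("mismatch", "A")} for r in range(4)}
    events[4] = {5: ("mismatch", "T")}
    pile = _as_pileup(_columns(draft, events, n_reads=10))
    cand = CandidateError("c", 5, "substitution", 1, "G", "T")
    out = confirm_substitution(cand, pile, PolishConfig(), {"c": draft})
    assert out.status == "confirmed"
    assert out.correction_seq == "A"  # reads outvote the reference suggestion
    assert out.read_adp == pytest.approx(0.4)


@pytest.mark.parametrize("n_support,expected", [(0, "removed"), (1, "confirmed")])
def test_substitution_threshold(n_support, expected):
    draft = "GCGCTGGCTAGC"
    events = {r: {5: ("mismatch", "A")} for r in range(n_support)}
    pile = _as_pileup(_columns(draft, events, n_reads=10))
    cand = CandidateError("c", 5, "substitution", 1, "G", "A")
    out = confirm_substitution(cand, pile, PolishConfig(), {"c": draft})
    assert out.status == expected  # 1/10 = 0.10 meets the lenient threshold


def test_adjust_all_without_reads_drops_substitutions_keeps_indels():
    errors = [
        CandidateError("c", 5, "substitution", 1, "G", "A"),
        CandidateError("c", 20, "deletion", 1, "", "T"),
        CandidateError("c", 40, "insertion", 2, "AT", ""),
    ]
    out = adjust_all(errors, None, PolishConfig(), {"c": "A" * 50})
    by_type = {e.error_type: e.status for e in out}
    assert by_type["substitution"] == "removed"
    assert by_type["deletion"] == "retained_unsupported"
    assert by_type["insertion"] == "retained_unsupported"
    assert adjust_all([], None, PolishConfig(), {}) == []


def test_adjustment_invariants_on_synthetic_world(zero_world):
    """Types never change, splits conserve length, positions stay inside
    the 21 nt window, indel count never decreases."""
    from refpolish.detection import detect

    cfg = PolishConfig()
    candidates = detect(zero_world.ref_pileup, zero_world.draft, cfg)
    adjusted = adjust_all(candidates, zero_world.read_pileup, cfg,
                          zero_world.draft)
    n_indels_in = sum(e.error_type != "substitution" for e in candidates)
    indel_len_in = sum(e.length for e in candidates
                       if e.error_type != "substitution")
    out_indels = [e for e in adjusted if e.error_type != "substitution"]
    assert len(out_indels) >= n_indels_in
    assert sum(e.length for e in out_indels) == indel_len_in
    assert sum(e.error_type == "substitution" for e in adjusted) <= \
        sum(e.error_type == "substitution" for e in candidates)
    for e in adjusted:
        if e.original_position is not None:
            assert abs(e.position - e.original_position) <= cfg.adjust_window // 2


def test_mispositioned_candidates_relocate_to_true_site(zero_world):
    """Indel candidates shifted up to 3 nt within their homopolymer are
    pulled back to the canonical true site by read evidence."""
    rng = np.random.default_rng(17)
    cfg = PolishConfig()
    indels = [e for e in zero_world.truth_errors
              if e.error_type != "substitution"]
    shifted = offset_indels_within_runs(indels, zero_world.draft, rng, 3)
    moved = [(s, t) for s, t in zip(shifted, indels) if s.position != t.position]
    assert moved, "offset helper should displace at least one candidate"
    relocated = 0
    for s, t in moved:
        out = adjust_indel(s, zero_world.read_pileup, cfg, zero_world.draft)
        relocated += len(out) == 1 and out[0].position == t.position
    assert relocated / len(moved) >= 0.95
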