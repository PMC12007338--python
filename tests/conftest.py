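"""Shared fixtures and independent brute-force oracles.

The oracles recount ADPs directly from raw observations, independently of
the implementation under test, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from refpolish.model import Observation, PileupColumn
from refpolish.simulate import SimulationSpec, default_error_mix, simulate_world

BASES = "ACGT"


# ---------------------------------------------------------------------------
# brute-force oracles

def brute_positional_adp(column: PileupColumn, error_type: str,
                         max_indel_len: int = 2) -> float:
    """Direct per-definition recount of the positional ADP."""
    if column.depth == 0:
        raise ValueError("undefined at zero depth")
    n = 0
    for obs in column.observations:
        if error_type == "substitution":
            n += obs.kind == "mismatch" and obs.base != "N" \
                and column.draft_base != "N"
        elif error_type == "insertion":
            n += 0 < len(obs.deletion) <= max_indel_len
        else:
            n += 0 < len(obs.insertion) <= max_indel_len
    return n / column.depth


def brute_regional_adp(columns, window, error_type, trigger_pos,
                       max_indel_len: int = 2, length=None) -> float:
    """Exhaustive per-source enumeration of the regional ADP."""
    covering = {o.source for o in columns[trigger_pos].observations}
    hits = set()
    for source in covering:
        for pos in range(*window):
            for obs in columns[pos].observations:
                if obs.source != source:
                    continue
                if error_type == "substitution":
                    q = obs.kind == "mismatch" and obs.base != "N" \
                        and columns[pos].draft_base != "N"
                elif error_type == "insertion":
                    q = 0 < len(obs.deletion) <= max_indel_len \
                        and (length is None or len(obs.deletion) == length)
                else:
                    q = 0 < len(obs.insertion) <= max_indel_len \
                        and (length is None or len(obs.insertion) == length)
                if q:
                    hits.add(source)
    return len(hits) / len(covering)


def random_columns(rng: np.random.Generator, n_cols: int, n_sources: int,
                   contig: str = "c") -> tuple[str, list[PileupColumn]]:
    """A windowful of random pileup columns over a random draft, with every
    source covering every column and event kinds drawn freely."""
    draft = "".join(rng.choice(list(BASES), size=n_cols))
    cols = []
    for pos in range(n_cols):
        col = PileupColumn(contig=contig, pos=pos, draft_base=draft[pos])
        for src in range(n_sources):
            r = rng.random()
            if r < 0.55:
                kind, base = "match", ""
            elif r < 0.8:
                kind = "mismatch"
                base = BASES[(BASES.index(draft[pos]) + int(rng.integers(1, 4))) % 4]
            else:
                kind, base = "gap", ""
            ins = dele = ""
            if rng.random() < 0.15:
                ins = "".join(rng.choice(list(BASES),
                                         size=int(rng.integers(1, 4))))
            if rng.random() < 0.15 and pos < n_cols - 3:
                ln = int(rng.integers(1, 4))
                dele = draft[pos + 1:pos + 1 + ln]
            col.observations.append(Observation(
                source=src, kind=kind, base=base, insertion=ins, deletion=dele))
        cols.append(col)
    return draft, cols


# ---------------------------------------------------------------------------
# shared synthetic worlds (session-scoped: built once)

@pytest.fixture(scope="session")
def zero_world():
    """20 kb truth, 10 identical references, 20 injected errors, 30x reads."""
    return simulate_world(SimulationSpec(
        seed=11, genome_length=20_000,
        injected_errors=default_error_mix(20)))


@pytest.fixture(scope="session")
def divergent_world():
    """Same shape with strain-level reference divergence (~95% identity)."""
    return simulate_world(SimulationSpec(
        seed=12, genome_length=20_000, ref_sub_rate=0.02,
        ref_indel_rate=0.002, injected_errors=default_error_mix(20)))
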