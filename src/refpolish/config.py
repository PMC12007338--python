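"""Runtime configuration: every threshold and schedule knob in one place."""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True, slots=True)
class PolishConfig:
    """Thresholds and schedules for detection and read adjustment.

    Parameters
    ----------
    error_threshold
        Minimum regional alignment-difference probability (ADP) for a
        candidate error.  At the default 0.99 with <= 15 aligned references,
        every covering reference must exhibit the difference.
    regional_trigger
        Minimum positional ADP before a window-level regional ADP is
        computed (fraction of covering references differing at one column).
    min_ref_coverage
        Minimum number of covering reference genomes for a column to be
        assessed at all.
    max_indel_len
        Indels longer than this are treated as strain variants, not
        candidate errors, and ignored entirely.
    elective_passes
        Number of optional scan iterations after the two mandatory passes.
    third_pass_window
        Window width (nt) of the first elective pass; subsequent elective
        passes grow by ``window_growth`` nt per side.
    window_growth
        Per-side window growth (nt) per elective pass beyond the first.
    adjust_threshold_sub
        Minimum read ADP for a substitution candidate to survive.
    adjust_threshold_indel
        Minimum read ADP for an indel candidate site to count as
        read-supported during adjustment.
    adjust_window
        Width (nt) of the read-evidence window centred on a candidate.
    strategy_every
        The two elective search strategies (window shifting and
        alternative-length merging) are enabled on every ``strategy_every``-th
        elective pass.
    """

    error_threshold: float = 0.99
    regional_trigger: float = 0.25
    min_ref_coverage: int = 5
    max_indel_len: int = 2
    elective_passes: int = 4
    third_pass_window: int = 11
    window_growth: int = 5
    adjust_threshold_sub: float = 0.10
    adjust_threshold_indel: float = 0.25
    adjust_window: int = 21
    strategy_every: int = 2

    def __post_init__(self) -> None:
        for name in ("error_threshold", "regional_trigger",
                     "adjust_threshold_sub", "adjust_threshold_indel"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("third_pass_window", "adjust_window"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {v}")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")
        if self.min_ref_coverage < 1:
            raise ValueError("min_ref_coverage must be >= 1")
        if self.elective_passes < 0:
            raise ValueError("elective_passes must be >= 0")
        if self.window_growth < 0:
            raise ValueError("window_growth must be >= 0")
        if self.strategy_every < 1:
            raise ValueError("strategy_every must be >= 1")

    @property
    def total_passes(self) -> int:
        """Two mandatory passes plus the elective schedule."""
        return 2 + self.elective_passes

    def asdict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
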