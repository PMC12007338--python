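"""End-to-end orchestration: detect -> adjust -> correct."""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .adjustment import adjust_all
from .config import PolishConfig
from .correction import apply_errors
from .detection import detect
from .model import CandidateError, Pileup

logger = logging.getLogger("refpolish")


@dataclass(slots=True)
class PipelineResult:
    candidates: list[CandidateError]  # raw detection output
    errors: list[CandidateError]  # after read adjustment
    corrected: dict[str, str]

    def status_counts(self) -> Counter:
        return Counter(e.status for e in self.errors)

    def type_counts(self, applicable_only: bool = True) -> Counter:
        return Counter(e.error_type for e in self.errors
                       if e.applicable or not applicable_only)


def run_pipeline(draft: dict[str, str], ref_pileup: Pileup,
                 read_pileup: Pileup | None = None,
                 secondary_pileup: Pileup | None = None,
                 config: PolishConfig | None = None) -> PipelineResult:
    """Detect candidate errors against the reference pileup, adjust them
    with read evidence (or apply the no-reads policy), and correct the
    draft."""
    config = config or PolishConfig()
    candidates = detect(ref_pileup, draft, config, secondary_pileup)
    logger.info("detected %d candidate errors", len(candidates))
    errors = adjust_all(candidates, read_pileup, config, draft)
    counts = Counter(e.error_type for e in errors if e.applicable)
    logger.info(
        "final errors: total=%d insertions=%d deletions=%d substitutions=%d",
        sum(counts.values()), counts["insertion"], counts["deletion"],
        counts["substitution"],
    )
    corrected = apply_errors(draft, errors)
    return PipelineResult(candidates=candidates, errors=errors,
                          corrected=corrected)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: PolishConfig, inputs: dict[str, object],
                   result: PipelineResult | None = None) -> None:
    """Record the effective configuration, input checksums and outcome
    counts of one run."""
    manifest: dict[str, object] = {
        "config": config.asdict(),
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in inputs.items() if p is not None},
    }
    if result is not None:
        manifest["errors_by_status"] = dict(result.status_counts())
        manifest["errors_by_type"] = dict(result.type_counts())
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
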