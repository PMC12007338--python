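# refpolish

Reference-comparative detection and correction of gene-fragmenting errors
in small-genome long-read draft assemblies.

Long-read (nanopore) assemblies of bacterial and small eukaryotic genomes
are highly contiguous but still carry sparse 1–2 nt indels, concentrated
in homopolymers, that frameshift and pseudogenize otherwise intact genes.
The usual fix needs extra sequencing (short reads, signal-level
polishing).  `refpolish` instead exploits data that already exists in the
public space: a curated set of ~10 related reference genomes locally
aligned to the draft.  Positions where essentially *all* aligned
references disagree with the draft in the same way are far more likely to
be assembly errors than shared biology, and correcting them defragments
genes without any new sequencing.  Raw reads, when available, are used
only to confirm or reposition candidates, keeping the corrections
faithful to the sequenced strain rather than to any reference.

## Method

All evidence is consumed as an all-positions `samtools mpileup`-style
text pileup of the reference alignments (and optionally of the raw reads)
against the draft.  For each error type *e* ∈ {substitution, insertion,
deletion} at draft position *i*, the **alignment difference probability**
is the fraction of covering references showing that difference:

    ADP_e(i) = (# references differing from the draft by e at i) / (# references covering i)

Error types are named from the draft's perspective: a reference *deletion*
signals a spurious **insertion** in the draft, a reference *insertion*
signals a **deletion** from the draft.  Indels longer than 2 nt are treated
as strain variants and ignored.  Detection scans every position over a
multi-pass window schedule (width 1, then the homopolymer extent, then
11 nt growing by 5 nt per side), requiring

* coverage of ≥ 5 references,
* a positional ADP ≥ 0.25 to open a window, and
* a **regional ADP** ≥ 0.99 — computed over the window with each reference
  counted at most once — to call a candidate.

Candidate sites inside a window are scored as
`score = mismatch frequency × homopolymer length` (halved when the implied
correction would split a run), merged within a run, and the best-scoring
site is emitted.  With a read pileup, each indel candidate is then
confirmed, relocated to the best read-supported equivalent within a 21 nt
window (≥ 25% of reads), split 2 nt → 1 nt + 1 nt, or retained
unadjusted — indels are never dropped; substitutions require ≥ 10% read
support for a single replacement base and are removed otherwise.  The
finalized list is applied to the draft in descending coordinate order and
written as a TSV that reproduces the corrected FASTA exactly without
re-running detection.

A built-in simulator generates seeded test worlds (truth genome,
error-injected draft, strain-divergent references, reads) with alignments
derived exactly from the known edits, so the whole stack is testable with
no aligner or download.

## Worked example

`examples/01_polish_synthetic_assembly.py` builds a 100 kb world with 50
known injected errors, ten references at ~95% pairwise identity and 30×
reads, then polishes the draft:

```
draft: 99,975 nt, 50 injected errors, 10 references, 30x reads
detected candidates: 54
final errors: total=50 insertions=10 deletions=30 substitutions=10
status trail: {'confirmed': 50, 'removed': 4}
sensitivity: 100.0%  false candidates: 0
corrected assembly equals truth genome: True
```

All 50 injected errors are recovered; the four extra substitution
candidates raised by reference strain variation lack read support and are
removed before correction; the polished FASTA is base-for-base identical
to the genome the draft was derived from.  The other examples profile the
sequence context of detected errors (homopolymer-biased deletions) and
demonstrate the no-reads policy and secondary-reference supplementation.

The same workflow is available from the shell:

```sh
refpolish simulate --seed 1 --outdir world
refpolish run world/draft.fasta world/references.mpileup \
    --reads world/reads.mpileup --outdir out
refpolish correct world/draft.fasta out/errors.tsv --out replay.fasta
```

`out/errors.tsv` lists every candidate with its ADPs, score, read support
and status trail (`detected`/`confirmed`/`adjusted`/`split`/
`retained_unsupported`/`removed`); `refpolish correct` re-applies it
byte-identically.

## Layout

- `src/refpolish/` — library: `io` (FASTA/mpileup/TSV), `detection`,
  `adjustment`, `correction`, `profiling`, `simulate`, `pipeline`, `cli`
- `examples/` — one short narrative script per capability
- `tests/` — unit, property and end-to-end suites
- `docs/methods.md` — models, parameters, design choices and limitations
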