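# Methods

## Problem setting and model

A draft assembly of a small genome is compared against a set of related
reference genomes locally aligned to it.  The working assumption is that
a 1–2 nt difference shared by *all* (or nearly all) references at one
site is far more likely to be an assembly error in the draft than a
coincident variant in every reference, because independent strains rarely
agree on small indels at a single position.  Conversely, long indels and
sites where references disagree among themselves are treated as biology
and left alone.  Raw reads from the sequenced strain, when available,
arbitrate between reference consensus and strain-specific variation.

All coordinates are 0-based half-open internally; the mpileup dialect and
the error-list TSV are 1-based.  Error types are defined from the draft's
perspective throughout: an *insertion* error means the draft carries
spurious bases (references show a deletion against the draft; the
correction removes the bases), a *deletion* error means the draft is
missing bases (references show an insertion; the correction inserts them
after an anchor base).  Indel evidence is anchored on the draft base
immediately preceding the event, the mpileup convention, and a
multi-base event contributes only at its starting anchor so overlapping
longer indels do not inflate per-position tallies.

## Detection

Per column and error type the positional alignment difference
probability (ADP) is the fraction of covering references exhibiting the
difference; gap placeholders (positions inside a declared deletion)
count as covering.  Columns need ≥ `min_ref_coverage` (default 5)
references; indels longer than `max_indel_len` (default 2 nt) are ignored
outright; 1 nt and 2 nt indels are tallied independently.  Columns whose
draft base is `N` are excluded from substitution detection (no correction
could be defined), and reference `N` bases count toward depth but never
toward a numerator.

The scan makes `2 + elective_passes` passes (default 6).  Window widths:
pass 1 is the single column (positional and regional ADP coincide, so
pass 1 *is* the direct threshold test); pass 2 spans the maximal
homopolymer run containing the column; pass 3 uses 11 nt centred, growing
by 5 nt per side each further pass.  A column whose best positional ADP
reaches `regional_trigger` (default 0.25) is expanded to the pass window
and a regional ADP is computed with each reference counted at most once,
however many differences it shows in the window.  The regional
denominator is the set of references covering the trigger column (blocks
may end mid-window); the numerator is restricted to that same set, so the
ratio is always in [0, 1].  A candidate requires regional ADP ≥
`error_threshold` (default 0.99, i.e. unanimous for ≤ 15 references).
All threshold comparisons are inclusive (≥): the boundary behaviour is
otherwise arbitrary, and inclusive comparisons keep "exactly at
threshold" cases deterministic.

Two extra search strategies run on every second elective pass (overall
passes 4, 6, …): window shifting evaluates the window re-anchored at its
left and right edge (only those two offsets, bounding cost), and
alternative-length merging lets references that disagree only on indel
length (1 vs 2 nt) support a common candidate.

Within a qualifying window every site carrying a same-type difference is
scored as `per-site reference fraction × homopolymer length`.  Sites of
the same correction type within one run are merged first (supports
deduplicated per reference; the representative is the best-supported,
leftmost on ties).  The homopolymer length is the maximal identical run
in the *draft* containing the site (for deletion errors, the run of the
would-be-inserted base adjacent to the anchor; 1 when the insertion
extends no run).  A correction that would place a non-matching base
strictly inside a run of length ≥ 2 is halved: such corrections break a
run in two and are rarer in practice than run-length adjustments.  The
best-scoring site wins; ties go leftmost.  The correction sequence is the
most frequent alternative among supporting references (lexicographically
smallest on ties).

Columns inside an emitted candidate's window are claimed **per error
type** and skipped on later passes: simple cases resolved early are never
revisited, while a combined substitution + deletion at one site still
surfaces as two adjacent candidates of different types.  An emitted
candidate also claims its own position, so no two candidates of one type
ever share a site.

When a secondary (larger, more diverse) reference pileup is supplied,
columns failing the primary coverage gate — and only those — are
re-evaluated against it with identical logic, preserving the primary
set's detection behaviour wherever it has coverage.

## Read adjustment

Each indel candidate gets a 21 nt read-evidence window centred on it
(truncated at contig ends).  Read ADPs are computed per site exactly as
for references, then sites within one homopolymer run carrying the same
error type and length are pooled into one representative site, since
every anchor along a run implies the same corrected sequence; the
canonical representative is the run-end anchor.  An event that breaks a
run (inserting a non-run base) stays independent.  Denominators are the
reads covering the representative site.

The initial candidate site is assessed first: with pooled read ADP ≥
`adjust_threshold_indel` (default 0.25) no alternative is considered and
the candidate is confirmed, its position snapped to the canonical run
anchor (an equivalent edit; the original position is recorded whenever
the coordinate changes).  Otherwise the best-supported same-type,
same-length site in the window takes over (`adjusted`); a 2 nt candidate
with no 2 nt support may split into the two best-supported 1 nt sites
(`split`, both sites must clear the threshold); failing everything the
candidate is `retained_unsupported` — indel candidates are never dropped,
because systematic homopolymer miscalls depress read support for true
indel errors.  Relocated and split candidates re-derive their correction
sequence from the read evidence at the new site, the strain-faithful
choice.  Substitutions are the opposite: among the three alternative
bases the best read ADP at the site must reach `adjust_threshold_sub`
(default 0.10) or the candidate is removed; the confirmed base is the
reads' choice even when it differs from the references' suggestion.
Without any read pileup, all substitution candidates are removed and all
indels pass through unadjusted.

## Correction and round trips

Edits are validated against the draft (a draft-sequence mismatch means a
stale list and is a hard error), checked for overlaps (overlap signals a
corrupt list; window claiming prevents it in normal operation), and
applied per contig in descending coordinate order so positions never
shift.  All TSV positions refer to original draft coordinates, which
makes the TSV alone sufficient to reproduce the corrected FASTA
byte-identically.  `invert_errors` produces the exact inverse edit list
in corrected-assembly coordinates, so corrections are reversible.

## Parameters

| knob | default | meaning |
|---|---|---|
| `error_threshold` | 0.99 | regional ADP to call a candidate (unanimity for ≤ 15 refs) |
| `regional_trigger` | 0.25 | positional ADP to open a window |
| `min_ref_coverage` | 5 | covering references required per column |
| `max_indel_len` | 2 nt | longest indel considered an error |
| `elective_passes` | 4 | scan passes beyond the two mandatory ones |
| `third_pass_window` | 11 nt | first elective window width |
| `window_growth` | 5 nt/side | window growth per further elective pass |
| `adjust_threshold_indel` | 0.25 | read ADP for indel support |
| `adjust_threshold_sub` | 0.10 | read ADP for substitution support |
| `adjust_window` | 21 nt | read-evidence window |

Raising `error_threshold` (e.g. 0.995–0.999) is appropriate for much
larger reference sets where strict unanimity becomes too brittle.

## The synthetic worlds

The generator emulates the regime the polisher targets rather than
general sequencing: a single-contig genome (default 100 kb, 59% GC,
matching a typical high-GC bacterial target), fifty injected draft errors
dominated by single-base homopolymer deletions with some 2 nt deletions,
insertions and substitutions, spaced ≥ 50 nt apart so detection windows
do not interact; ten references carrying independent per-reference
substitutions (rate 0.02/site) and 1–2 nt indels (0.002/site), giving
~95% pairwise reference identity, i.e. strain level; and reads of 2 kb at
30× whose error model is per-base substitutions (0.01) plus
homopolymer-length miscalls whose probability grows with run length.
Alignments of references and reads to the draft are *computed from the
recorded edit coordinates* and serialized as all-positions mpileup text —
no heuristic aligner — so every pileup event is re-derivable from the
recorded edits and parsing round trips are exact.  Reference divergence
is excluded within 10 nt of injected sites to keep ground truth
unambiguous, and homopolymer indels are canonically anchored at the end
of their run, defining a unique "true site" inside an otherwise
position-ambiguous run.

What the worlds do **not** model: real aligner behaviour (block
boundaries from alignment scoring, left-shifted indel placement),
read-length and quality distributions, chimeric or strand-specific
artefacts, coincident reference variation at injected sites, and
structural differences between references.  Passing tests therefore
demonstrate the correctness of the detection/adjustment/correction logic
under its stated assumptions, not field performance on any particular
organism, which depends on reference curation and alignment quality.

An independent alignment route (`pileup_from_alignment`, via edlib
global alignment) converts real alignments of whole references against
an assembly into the same pileup model; it cross-checks the generator on
identical sequences and supports idempotence checks on corrected
assemblies.

## Numerical and degenerate-input choices

Ties everywhere resolve deterministically (leftmost site,
lexicographically smallest sequence), and output lists are sorted by
(contig, position, type), so identical inputs give byte-identical
outputs.  Windows truncate at contig ends; candidates near contig ends
remain allowed; a deletion-error anchor of −1 prepends to the contig.
Depth-zero columns are representable (the all-positions contract) and are
excluded by the coverage gate.  Floats in the TSV are written with
`repr`, which round-trips exactly.  Pileups that violate slot consistency
(segment counts not matching open segments) are rejected rather than
guessed at.  A reference genome aligned in several blocks is counted per
block; blocks of one genome cannot overlap a column, so per-column
deduplication is unaffected.

## Known limitations

Sensitivity is bounded by reference coverage and diversity: regions
covered by < 5 references are silent (a secondary set can reclaim part of
this), and highly diverse reference sets mask true errors by breaking
unanimity.  Errors longer than 2 nt and structural problems are out of
scope by design.  Clustered errors closer than a detection window
interact through window claiming and may resolve in a later pass or not
at all; the simulator's spacing default sidesteps this, and a stress
configuration can lift it.  Memory holds the full pileup per contig, so
the tool suits small genomes (roughly ≤ tens of Mb).
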