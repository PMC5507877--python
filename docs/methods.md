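# Methods

## The library model

A *fragment* is the unit recovered after adapter removal: the amplified
target plus its constant flanking spacers (default 120 + 33 + 34 = 187 bp;
all lengths configurable through `ArchitectureSpec`). A *monomer* is a
fragment with one copy of the concatenation adapter on each end,
`x = fragment + 2·y` with adapter length `y` (default 30, giving
`x = 247`). Assembly joins monomers at complementary adapter ends, so
adjacent adapter copies merge and an n-mer has expected length

```
L(n) = n·x − (n−1)·y = n·(x−y) + y
```

equivalently *n* fragments plus *n + 1* adapters. Two consequences are used
as internal checks throughout the package: each added unit contributes
exactly `x − y` bases, and read length regressed on unit count has slope
`x − y` and intercept `y`.

The bundled default adapter is this package's own 30 bp sequence designed
to the published constraints for efficient isothermal assembly — GC
fraction exactly 0.40 (12/30), no homopolymer run above 2 — plus one
constraint the scanner needs: edit distance 12 between the adapter and its
own reverse complement, so orientation calls cannot collide at any scan
threshold ≤ 6. The adapter is a required, configurable input to every
stage; nothing is specific to the bundled sequence.

`scaleup_factor(q) = 1/q` answers the library-scale question: if size
selection keeps only the fraction `q` of molecules (e.g. q = 0.079 for
reads with ten or more fragments), `1/q ≈ 12.7` times more concatenated
input must enter the selection for the retained population alone to match
the original library amount.

## The simulator: what it emulates, and what it does not

`simulate` emits consensus-level reads directly — the error profile of a
circular-consensus read, not of raw polymerase passes. A read is built as

```
[remnant] adapter unit_1 adapter unit_2 … adapter unit_n adapter [remnant]
```

with units drawn i.i.d. from the panel (uniformly, or by an optional
weight vector for non-equimolar pools), each unit reverse-complemented
with probability 0.5 together with its flanking adapter context — so
adapter orientation switches along the read exactly as in real
concatemers. Artifact events mirror the structures seen in real libraries:

* **hairpin remnants** — a single A or T outside each terminal adapter,
  probability 0.4 per end (a ligation leftover of the sequencing hairpin);
* **terminal truncation** — each outermost adapter is cut to a uniform
  1..y−1 remaining bases with probability 0.3;
* **hybrid junctions** — with probability 0.005 per internal junction the
  adapter is omitted and the downstream unit loses a uniform 5–20 bp
  "chewed" overlap, emulating exonuclease-driven homology fusion;
* **errors** — independent per-base substitution/insertion/deletion at
  0.006/0.002/0.002 (≈1% total, the accuracy scale of multi-pass
  consensus reads), applied last.

Units per read follow either a fixed count or a geometric law with mean 5
clipped at 50. The geometric shape is a modeling choice: empirical
unit-count distributions are reported for real runs but no generative law
is published, so the default reproduces the observed scale (most reads
carrying roughly three to seven fragments, rare reads above fifty) without
claiming to be the true process. Spacer sequences are constant per design;
since no published spacer sequence exists they are drawn once,
deterministically, from the config seed (overridable). Qualities are
constant Q30 placeholders — no downstream stage consumes them.

Ground truth per read records unit composition, per-interval coordinates
(fragments, adapters, remnants — they tile the error-free read exactly),
applied variants and artifact events, in a tab-separated sidecar with
0-based half-open coordinates. Truth coordinates refer to the error-free
read; round-trip tests that compare coordinates therefore run with zero
error rates, and noisy-data tests compare counts, not coordinates.

What passing tests on this generator do **not** show: performance on real
consensus reads with context-dependent indel error, quality-correlated
errors, chimeric ZMW artifacts, or panels with homologous amplicons.

## Deconcatenation semantics

The scanner is deliberately simple and fully specified, so an independent
oracle can reproduce it:

1. A fixed window of the adapter length slides left to right. At position
   `p` the window `read[p:p+w]` is compared to the adapter and its reverse
   complement by unit-cost Levenshtein distance (global, both strings
   whole). Forward wins exact ties.
2. If the better distance is ≤ `k` (default 4), the scanner probes the
   next `k` positions and accepts the window with the smallest distance,
   leftmost on ties. This refinement matters: a window overlapping the
   true occurrence by `e` bases already scores `2e` (e deletions plus e
   missing adapter bases), so plain first-acceptance would fire up to
   `k//2` bases early and shift every boundary. Scanning resumes at the
   accepted window's end.
3. Near the right end, windows of length `m ≥ 10` are compared against
   the adapter *prefix* of length `m` in both orientations (a truncated
   terminal adapter keeps its inner bases) at the proportional threshold
   `ceil(k·m/w)`, with the same refinement. Reads shorter than 10 bases
   are emitted as a single fragment unscanned. Truncated adapters at the
   read *start* are intentionally left in place — they surface as
   oversized first fragments and are recovered by
   `classify.detect_partial_adapter`.

Hit coordinates are always the fixed window coordinates, so adapters and
the fragments between them partition the read exactly; the ≤4-base
occupancy slack an indel-containing adapter can have is absorbed by the
expected-size band downstream.

For speed, windows are pre-screened by a sound pigeonhole filter: within
`k ≤ 4` edits of a 30 bp adapter, at most 4 edit events split ≥ 26 matched
positions into ≤ 5 runs, the longest of which is ≥ 6 — so every true
window shares an exact 6-mer with the adapter. Only windows containing
such a 6-mer are scored (with edlib). The filter cannot reject a true
window; it is switched off automatically when the guaranteed shared-word
length falls below 6, as in the relaxed 6-edit rescan. The test suite
contains an independent oracle (full DP at every position, no filtering,
no edlib) and asserts exact equivalence on randomized reads with planted
adapters at edit loads 0–6.

A consequence of one-sided terminal handling is that scanning is not
perfectly mirror-symmetric at read ends; the symmetry property is asserted
for reads whose termini are intact adapters.

## Fragment classification

Only length-1 fragments (hairpin remnants) are removed before alignment.
The expected-size band defaults to 181–190 bp for the 187 bp design and
scales as `(fragment_len − 6, fragment_len + 3)` for other architectures;
fragments above the band are *oversized*, the rest *undersized_other* —
every fragment receives exactly one label.

`detect_partial_adapter` explains oversized terminal fragments: adapter
suffixes at a fragment's read-start edge and prefixes at its read-end
edge are tested at lengths `min_prefix..y` in both orientations. Stubs are
held to the scanner's per-base stringency (`ceil(4·m/30)` edits at tested
length `m`); a full-length tested adapter — which the strict scan must
have missed — is re-admitted at the relaxed 6-edit threshold, mirroring
`relaxed_rescan`. Stubs shorter than `min_prefix = 8` are below the
detection floor: a 4–7 bp leftover makes a fragment oversized but cannot
be distinguished from sequence context, so such fragments legitimately
carry no evidence. At the scaled thresholds, chance matches on
adapter-free fragments exist but are rare (the suite bounds them below
10% per fragment with both ends tested); evidence is therefore attached
only to oversized terminal fragments, where the prior is high.

## Alignment, hybrids, pileups

References are the spacer-free amplicon sequences; fragments keep their
spacers and the aligner clips them. Alignment is local (Smith–Waterman,
affine gaps) with match +2, mismatch −3, gap open −5, gap extend −2,
where "open" is the score of the first gap base (a length-g gap scores
−5 − 2·(g−1)). The engine is Bio.Align's pairwise aligner; traceback is
its canonical first path, which is deterministic for a fixed biopython
version (score ties between amplicons resolve by panel order, forward
before reverse). Two shortcuts never change results on their domain: an
exact full-reference occurrence in the query is taken directly (it is an
optimal local alignment and cannot be beaten by any equal-or-shorter
reference), and — following seed-and-extend practice — a (sub)query is
only aligned at all if it shares an exact 12-mer with the panel on either
strand.

A fragment's best passing alignment (identity ≥ 0.8 over alignment
columns, ≥ 50 aligned query bases) is its *primary*; query stretches of
≥ 25 bases outside the accepted intervals are re-aligned to the whole
panel and become *secondaries* (≥ 25 aligned bases at the same identity).
Role and orientation are bijective with SAM flags 0/16/256/272. The
identity/length thresholds are this package's choices — published run
statistics do not state the aligner's acceptance rule, which is why real
on-target rates are not treated as reproducible targets here.

A multi-aligned fragment is a **hybrid** iff the relaxed (≤ 6 edit)
adapter rescan finds no adapter between the aligned query intervals
(± 8 bp slack). If a heavily mutated adapter *is* found there, the
fragment is rescued: split at the adapter and re-mapped — the same
two-outcome logic applied to multi-aligned fragments in the original
workflow, reproduced as a mechanism rather than as counts.

Pileups count the query base at every covered reference position of
primary alignments; deletions occupy a fifth channel so that depth equals
the column sum, and insertions are ignored (standard pileup convention).
Allele frequency is `alt count / depth`; zero-depth positions are reported
with undefined AF rather than dropped. Amplicon coverage is the fraction
of primary alignments per amplicon.

## Run statistics

*Degree of concatenation* = fragments (after the 1 bp filter) / reads.
*On-target rate* = fragments with a primary alignment / fragments.
Reports round the degree to 2 decimals and rates to 1 decimal (the
conventional presentation); machine-readable lines keep full precision.
Cross-stage count mismatches raise instead of being silently reconciled.

## Validation scale and statistical checks

The acceptance-level tests run the full pipeline at sizes chosen to make
the statistical assertions sharp while keeping the suite quick: 1,000
clean mixed-n-mer reads for exact truth recovery; 500 randomized ≤ 1 kb
reads for scanner/oracle equivalence; 400 reads at 1% error for junction
recovery (≥ 99%) and the length-vs-count regression; 50 replicates of a
560-read, fixed 8-mer, two-amplicon library (per-variant depth ≥ 2,000)
for allele frequencies at 1%, 5%, 10% and 24.5%; and 2,000 reads at a
0.5% per-junction fusion rate for hybrid calling. Interval checks use
exact binomial quantiles; for the replicated AF study the pooled count per
frequency must fall in the exact 99% interval at the pooled depth and at
least 90% of replicates in their own — 200 independent 99% tests would be
expected to produce a few excursions even for a perfect estimator, so
"all within" is deliberately not asserted.

## Known limitations

* The scanner's fixed-window coordinates can be off by the indel imbalance
  of an adapter occurrence (≤ 4 bases at k = 4); fragment sizes absorb
  this by design, but base-resolution adapter boundaries under indels are
  not guaranteed.
* Secondary-alignment detection requires a 12-base exact anchor and ≥ 25
  aligned bases; fusions trimmed below that, or hybrids between highly
  similar amplicons, can escape hybrid calling.
* The simulator's error model is i.i.d. per base; homopolymer-biased
  indels typical of single-molecule chemistry are not modeled.
* Panels with near-duplicate amplicons will produce ambiguous primaries
  resolved by score then panel order; no mapping-quality model exists.
* The truncated-geometric unit-count law and the artifact rates are
  defaults for testing, not estimates of any particular instrument run.
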