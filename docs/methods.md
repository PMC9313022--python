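# Methods

This note documents the models and procedures implemented in `splicescan`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## Background and scope

Olduvai (DUF1220/NBPF) protein domains are encoded by exon doublets: a
small first exon — most often 52 nt — and a larger second exon.  In
expanded human-lineage-specific (HLS1) sub-types the first exon is 109 nt:
it carries a purine-rich insertion created by an intra-exon duplication of
a 33-nt block, and the region around the duplication (a 68-nt segment
called pG4 here) is predicted to fold into an RNA G-quadruplex even though
its G-runs are too short for the canonical motif.  The package quantifies
four sequence-level signals of this architecture: per-nucleotide splicing
enhancer/silencer activity, windowed G-quadruplex propensity, intra-exon
duplication structure, and region-versus-background score statistics.  A
seeded generator of synthetic doublet architectures provides ground truth
for every stage, so the whole pipeline is testable without any downloads.

## Per-nucleotide ESE/ESSseq profiles

A hexamer score table assigns one real splicing-activity value to each of
the 4096 DNA hexamers (positive = enhancer-like, negative =
silencer-like; the strongest enhancer hexamer, AGAAGA, scores 1.034 on
the published scale).  The profile of a sequence assigns to position *i*
the arithmetic mean of the scores of all in-bounds hexamers covering *i*
(up to six).  This overlap-average rule is the only symmetric, window-free
assignment; edge positions use in-bounds hexamers only (no invented
flanking sequence).  Hexamers containing ambiguity codes are skipped and
reduce the position's coverage; a position with no scorable hexamer
carries NaN, never a silent zero, and every downstream statistic excludes
such positions explicitly.

Lookups are case-insensitive and treat U as T, so one DNA-hexamer table
serves both DNA and pre-mRNA sequence.  The real published table is an
optional external input and is never bundled; all tests run on synthetic
tables.

**Peaks.** Peak calling smooths the profile with a centred moving average
(default width 7 nt; width 1 disables smoothing — the default for
statistics, which must not silently depend on smoothing) and reports one
peak per maximal run of positions whose smoothed value strictly exceeds a
user-supplied baseline (the "control exon mean"; no default value is
hard-coded because none is universal).  Ties on a run's maximum resolve
to the centre of the tied stretch, so a rectangular bump peaks at its
middle.

## G-quadruplex propensity

Three predictors, applied to 60-nt windows advanced by 10 nt (the
screening defaults); windows anchor at 0 and a final full-length window is
emitted flush with the 3′ end when the last step does not land there; a
sequence shorter than the window is scanned as one whole-sequence window.

* **G4Hunter**: each base in a maximal run of *k* guanines scores
  +min(*k*, 4), in a run of *k* cytosines −min(*k*, 4), otherwise 0; the
  window score is the mean.  Call threshold > 0.9 (strict).  The score is
  antisymmetric under reverse complement.
* **cGcC**: ratio of consecutive-G over consecutive-C content, where a
  maximal run of length *n* contributes a run-length-dependent weight —
  each base in the run weighs 10·*n*, so a run contributes 10·*n*².  The
  weight table is data (`data/cgcc_weights.json`), not code, so the scheme
  can be corrected or replaced without touching the implementation.  When
  a window contains no C-run the denominator is the pseudocount 1 and the
  score equals the cG sum exactly.  Call threshold > 4.5 (strict).
* **Canonical motif**: G≥3 N1–7 G≥3 N1–7 G≥3 N1–7 G≥3, matched
  leftmost-shortest without overlap (lazy quantifiers); loops admit any
  nucleotide including N.  N otherwise scores 0 and breaks runs in both
  scorers.

The neural-network score of the same screening tool (threshold > 0.5) is
deliberately not implemented: it is trained-model weights, not a formula.
Scanning is sense-strand by default with a both-strands option; no
thermodynamic folding or metal-ion stability modelling is attempted.

## Intra-exon duplication detection

Direct repeats only, found by exhaustive offset scan: for each offset *d*,
positions *i* and *i+d* are compared and maximal runs with at most
`max_mismatch` Hamming mismatches are extracted.  A reported pair has
equal-length copies with `min_len ≤ length ≤ d` (the length cap keeps the
copies non-overlapping; a tandem repeat yields abutting intervals), is
maximal (one-base extension either way violates the budget, the bounds,
or the overlap constraint), and is not contained in a longer pair at the
same offset (different offsets are independent structures and all
reported).  Output is deterministic, sorted by length (desc) then
position.  Defaults `min_len=20`, `max_mismatch=2`: long enough that
random ~100-nt sequences rarely produce hits, short enough to always find
a 33-nt duplication.  Gapped alignment is not used: the target event's
copies are near-identical, so Hamming extension suffices.  The separator
between the copies is annotated with its length and purine fraction
(undefined for tandem pairs).

## Region-versus-background statistics

Scores inside a region of interest form sample *x*; the background is
either the whole profile (default — matching a comparison of a region
against the transcript average, region included) or its complement.  The
unpaired t-test is implemented from the textbook formulas (pooled Student
by default, Welch optional) with the two-sided p computed through the
regularized incomplete beta function; zero pooled variance is a hard
error.  Treating per-nucleotide scores as independent is optimistic —
overlapping hexamers correlate scores over ~6 nt — but is reproduced as
the method of record; `block_permutation_test` (block = 6 nt, the hexamer
footprint) is provided as the conservative alternative and is the one to
prefer for real inference.  The CLI refuses to batch per-interval tests
without an explicit `--no-correction` acknowledgement, because no
multiple-testing correction is applied.

## Synthetic gene models

`DoubletSpec` fixes the architecture; all lengths in nt, defaults:

| parameter | default | meaning |
|---|---|---|
| `first_exon_len` | 52 | unexpanded first exon |
| `insertion_len` | 57 | purine-rich insertion (52 + 57 = 109) |
| `dup_block_len` | 33 | duplicated block length |
| `separator_len` | 7 | purine motif between the copies |
| `pg4_len` | 68 | pG4-like region (last 68 nt of the expanded exon) |
| `insertion_purine_fraction` | 0.95 | hit exactly by composition bookkeeping |
| `g_run_max` | 2 | longest G-run allowed in the purine segment |
| `planted_mismatches` | 1 | substitutions between the two copies |
| `second_exon_len` | 150 | larger second exon (human internal exons average ~140 nt) |
| `intron_len` | 300 | short intron, as in recently duplicated genes |
| `flank_len` | 60 | flanking context either side |

The unexpanded exon is `[19-nt prefix][33-nt block A]`; the expanded exon
inserts `[separator][block A′][17-nt purine tail]` directly after A.  The
true overlap geometry between insertion, duplication and pG4 region is
not published as coordinates, so all offsets are parameters; the defaults
make the arithmetic exact (19 + 33 = 52, 52 + 57 = 109).  The pG4 region
can straddle the exon 3′ boundary via `pg4_exon_overhang` (default fully
exonic).

Construction details that matter:

* The purine segment is assembled from tiles (`GGA`, `GGAA`, `GA`) that
  always end in A, so no concatenation can exceed the G-run cap; the
  expected G4Hunter mean of the segment is ≈ 1.17, comfortably above the
  0.9 call threshold, while the cap at 2 makes the canonical G≥3 pattern
  structurally impossible.
* The insertion's purine fraction is exact: a fixed number of non-purines
  (one C planted near the centre of the pG4 region — a single cytosine
  mid-segment is part of the emulated motif — and T's in the tail) is
  placed into an otherwise all-purine multiset.
* Copy mismatches are purine↔purine substitutions, preserving both the
  purine fraction and the G-run cap.
* Every tile starts with G, so the bases flanking the planted pair would
  match and a Hamming extension would overrun the planted coordinates;
  the separator therefore starts with A and the prefix is forced to end
  off the separator's last base, pinning a budget-exhausted extension
  exactly at the block boundaries.  Exact coordinate recovery is
  guaranteed only at `max_mismatch == planted_mismatches`: any spare
  budget provably absorbs a flanking mismatch and extends the run.
* Generation self-checks all planted invariants (exact duplication
  recovery, canonical-scan emptiness, a G4Hunter-positive window over the
  pG4 region, exact purine fraction) and retries with a derived attempt
  seed on a random violation — across seeds 1–60 at the defaults, at most
  one retry is needed — failing hard after 50 attempts (which is how an
  unsatisfiable spec surfaces).

Seeding uses a splitmix64 derivation (`derive_seed`) for per-gene and
per-attempt seeds, so cohort subsets regenerate independently of cohort
size and all derived seeds stay below 2³¹.

**What the generator does not emulate:** real coding constraints, codon
structure, the 96–100 % inter-copy identity of real HLS exons across a
gene family, splice-site motifs, realistic intron length distributions,
and any recombination/expansion dynamics.  Background sequence is uniform
i.i.d. over ACGT.  Passing tests therefore demonstrate that the
*operations* are correct on architectures with the stated geometry and
composition, not that real genes exhibit the planted effect sizes.

## Numerical choices

* Coordinates are 0-based half-open everywhere internally and in BED/TSV
  outputs; 1-based appears only in human-readable summaries.
* Profile agreement with the brute-force oracle is required to 1e−12
  (identical arithmetic is not assumed; summation order may differ).
* Threshold calls are strict inequalities.
* The t statistic is exact closed form; p-values agree with numerical
  integration of the t density to better than 1e−6 (observed ~1e−11).
* Degenerate inputs fail loudly: sequences shorter than a hexamer,
  empty/all-missing intervals, zero-variance samples, incomplete score
  tables, planted scores off the published scale.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 200 random
sequences (6–80 nt) for the profile oracle, 100 random sequences
(16–60 nt, `min_len=8`) for the duplication oracle, 20 planted expanded
genes for architecture recovery and region statistics, 1000 null
simulations for type-I error calibration, and 500 random sequences for
G4Hunter antisymmetry.  These sizes give stable results (type-I rate
0.04–0.05 across seeds) while the whole suite runs in well under a
minute.

## Known limitations

* The cGcC run-weight scheme is transcribed from its defining
  publication's description; the reference screening tool was not run for
  cross-validation, so the fixture values checked in tests are
  hand-computed under the stated weights (and the weight table is
  swappable data for exactly this reason).
* The t-test's independence assumption is wrong for overlapping-hexamer
  profiles; use the block-permutation option for conservative inference.
* Duplication detection is ungapped; an indel between copies splits a
  pair in two.
* Whether a transcript-wide average should include introns is
  analysis-dependent; both background modes are exposed and reported.
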