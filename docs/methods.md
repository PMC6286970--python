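# Methods

## Profiles and encodings

A structure profile is a finite real vector, one score per nucleotide;
sign encodes state (positive = paired, negative = unpaired), magnitude
encodes confidence. Three encodings are ingested:

* **Score tables** (TSV `position<TAB>score`, 1-based contiguous): taken
  as-is, full float precision preserved on round trip.
* **Dot-bracket**: every bracket (`()[]<>`, each kind balanced) maps to
  +1, dots to −1. We standardize binary encodings on ±1 rather than 1/0
  so the sign convention holds uniformly across sources.
* **SHAPE reactivities** (two-column, −999 = missing): reactivity below a
  threshold → +1, at/above → −1, missing → 0. The threshold defaults to
  0.5 reactivity units, a conventional paired/unpaired cut; it is a
  parameter, not a constant of nature. Missing values map to the neutral
  0 rather than being dropped so profile length always equals transcript
  length.

`ds_only_transform` clips negative scores to 0, restricting comparisons to
double-stranded signal (stems are more conserved than loops; loop-only
signal tends to inject noise). Applied to a binary dot-bracket track the
output is {0, +1} and is relabelled as a generic score track, since the
strict ±1 binary contract no longer holds.

Smoothing (centered moving average, default window 51 nt, truncated at the
edges) exists for plots and reports only; distances are always computed on
the raw track.

## The warping distance

Local cost is the Manhattan (absolute) difference of scores. The dynamic
program uses the asymmetric step pattern {(1,0), (1,1), (1,2)} with unit
weights: the query index advances exactly once per step. Consequences:

* a path always has exactly N steps, so open-end minimization over ending
  positions compares costs accumulated over the same number of steps;
* in standard (end-to-end) mode the final cell is reachable only when
  M ≤ 2N−1; larger M raises a "no admissible warping path" error rather
  than silently returning nonsense;
* standard mode warns (never fails) when the length ratio reaches 3×,
  where the open-begin/end mode is the better instrument.

**Normalization.** The default divides the accumulated cost by N+M,
normalizing for the lengths of both profiles; `query_length` (the
classical asymmetric-pattern normalizer, cost/N) and `reference_length`
are provided for users who want the textbook convention. The choice
rescales distances but, for fixed query length, not their ranking.

**OBE mode.** Open begin: the first query position may sit anywhere on
the reference (`D(1, j) = |q_1 − r_j|` for all j). Open end: the reported
cost is the minimum of the last row. Ties on the ending index break toward
the smallest index, then toward the shortest matched interval (predecessor
ties prefer the smallest reference advance). If the caller passes a longer
query, query and reference are swapped and the swap is recorded in the
result rather than erroring. Matched coordinates are reported 1-based
inclusive on the reference.

The full predecessor matrix is stored for backtracking (uint8, N×M); at
desk scale (tens of kilobases) this is a few tens of megabytes at worst.

**Oracle.** `brute_force_dtw` enumerates every admissible step sequence
(and every begin/end in OBE mode) on tiny instances (N ≤ 7). The test
suite checks exact agreement with the dynamic program on hundreds of
random instances; the oracle shares no code with the DP.

## Homology search

**Fragmented scan** cuts the query into consecutive non-overlapping
windows (default 200 nt, the conventional size for structural domains in
large RNAs) and OBE-searches each in the target. A trailing remainder of
at least half a window becomes a short final fragment; a smaller remainder
is merged into the previous fragment, avoiding spuriously tiny fragments
whose normalized distances are noisy. Inputs below 600 nt trigger a
warning (fragmentation is of little value there), never an error.

**Dataset scan** ranks one query against a collection: per pair the
shorter profile is OBE-searched within the longer; results sort by
ascending normalized distance with ties broken lexicographically by target
id. Full alignments are retained for the top k targets (default 20),
bare distances for the rest, so distance-vs-identity scatters over whole
collections stay cheap. Matched intervals export as 1-based TSV (primary)
and 0-based half-open BED.

## Significance

P-values are empirical. Calibration samples molecules into length classes
(defaults 200, 500, 1000, 5000 nt; 100 per class), assigns off-grid
lengths to the nearest class in log-length space, and stores all pairwise
OBE distances within and between classes. An observed distance against the
null of the nearest class pair gives

    p = (1 + #{null ≤ obs}) / (1 + n_null),

the add-one pseudocount keeping p strictly positive and honest at small n.
Classes with fewer than 30 assignable molecules (or `per_class` below 30)
are rejected at build time. Null distances are computed with the same mode
(OBE) and normalization as the analyses they calibrate. Nearest-class
lookup (rather than interpolation between classes) is a deliberate,
documented choice.

The **shuffling control** re-aligns the query against n shuffles of the
reference and reports the fraction of shuffles scoring at or below the
true distance. Block shuffling (default block 10 nt) is the default
because it preserves the segment-level autocorrelation that a re-predicted
shuffled sequence would retain; pointwise shuffling is available and is
the harsher null.

Distances ≥ 0.10 are annotated "different" in reports — an annotation
calibrated on real-molecule distance scales, never a hard filter. On the
synthetic generator's scale unrelated pairs can score below 0.10 (short
queries always find some sub-interval of a long reference), which is
precisely why the empirical p-value, not the raw distance, carries the
significance statement.

## Evaluation instruments

* **Global identity**: Needleman–Wunsch global alignment, match +5 /
  mismatch −4 (the dominant entries of the EDNAFULL matrix; ambiguity
  codes always score as mismatch — a documented simplification affecting
  only ambiguous-base inputs), affine gaps (open 10, extend 0.5 per
  additional gap position), terminal gaps free. Identity = identical
  columns / full alignment length including gap columns, as a percentage.
  The alignment itself is delegated to biopython's `PairwiseAligner`;
  a brute-force alignment enumerator in the tests independently verifies
  both optimality and the identity value on toy pairs.
* **Min-distance AUC**: each benchmark item is scored by its minimal
  normalized distance to any reference (ties to the lexicographically
  smallest reference id); the AUC of that score (lower = more positive)
  uses the Mann–Whitney midrank formulation, cross-checked in tests
  against scikit-learn's ROC integration.
* **Warped correlation**: Pearson correlation of the two score tracks
  sampled along the optimal path; undefined (error) when either track is
  constant along the path.

## Synthetic data

The generator emulates the stem/loop texture of predictor tracks with a
two-state Markov segment process: geometric segment lengths (paired mean
`mean_stem_len`, default 8 nt; unpaired mean set so the stationary paired
fraction equals `stem_density`, default 0.5), scores drawn as
±|N(0.5, 0.25)| clipped to magnitude [0.01, 2]. Folding the Gaussian into
the segment's sign (instead of letting the band leak across zero) makes
the positive fraction equal the paired fraction exactly, and the magnitude
floor keeps the sign convention meaningful at every position. The band
parameters loosely match the dynamic range of real predictor output.

Divergence is modelled as Gaussian score noise plus optional sign flips —
"same segmentation, perturbed scores", the profile-space analogue of
sequences that diverge while conserving structure. Motif embedding
overwrites a background slice and records the truth interval; overlap
against truth is measured as |intersection| / |truth|.

The retrieval benchmark (default 25 references / 25 positives /
25 negatives around one true motif, default 200 nt) uses independent
perturbations as references/positives and block shuffles of the motif as
negatives.

What the generator does **not** emulate: real base-pairing constraints
(no underlying fold exists), predictor-specific error structure,
length-dependent composition of real transcriptomes, and GC-content
effects. Passing tests therefore demonstrate the correctness and
calibration of the *instruments*, not organism-level conclusions.

## Problem sizes and numerical choices

Test and demonstration runs use scaled designs chosen for quick desk
iteration: null calibration in the suite uses length classes 100/200 nt
with 30 molecules per class (the library default keeps 200/500/1000/5000 ×
100); localization studies use 200-nt motifs in 2000-nt backgrounds over
100 seeds; benchmarks use the 25/25/25 design at motif length 200.
All randomness flows through `numpy.random.default_rng` seeds; every
generator is bit-reproducible under its seed. Costs and distances are
float64 throughout; the self-alignment distance is exactly 0.0 (no
tolerance needed) because the diagonal path accumulates exact zeros.

Known limitations: no banded/windowed DTW speedups, so all-vs-all scans of
many multi-kilobase profiles are quadratic per pair; no multiple-profile
alignment; step patterns other than asymmetric are out of scope.
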