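# Methods

This note records the models the package implements, the parameters that
matter, the choices made where the underlying procedures are underspecified,
and what the synthetic data does and does not establish.

## Synthetic ground truth

The generator (`physmap.truth`) draws a linear chromosome arm in kb
coordinates (0-based, half-open intervals; fractional positions are
kb / arm length, matching how deletion-bin labels are written).

* **Band sites** are a homogeneous Poisson process at `band_density`
  (default 0.83 sites/kb, giving ~107 bands per 129 kb clone) with true
  fragment sizes uniform on `band_size_range` (default 50–500 bp).
* **Clones.** Starts are uniform on `[0, length − insert]`; insert sizes
  are Normal(129, 29) kb with values below 10 kb redrawn (a truncated
  normal is an assumption — only the mean and SD of real insert sizes are
  known). The default clone count (65,413) is the subset of the arrayed
  library that yields usable fingerprints, ~15.7x coverage; fingerprinting
  failures themselves are not modelled.
* **Fingerprints.** A clone's fingerprint is the fragment sizes of band
  sites inside its interval, each dropped with `drop_rate`, jittered with
  Gaussian SD `size_jitter_sd`, plus Poisson-many spurious bands uniform
  in the size window; everything is clipped to the window. Sizes are
  emitted in **mobility units of 0.01 bp** (`SIZE_SCALE = 100`): capillary
  sizing resolves fragments to ~0.01 bp, which is the only reading under
  which the canonical matching tolerance of 12 and gel length of 60,000
  are coherent (0.12 bp and 600 bp respectively). Band identity is
  size-only; downstream code never sees site identities. Default noise is
  2% drops, 2% spurious bands, jitter SD 3 units (0.03 bp).
* **Genes.** Expected density rises linearly centromere→telomere
  (`density_gradient`, default 1:2, mirroring the observed two-fold
  bin-level gradient); with probability `island_clustering` (default 0.5)
  a gene is instead placed within one mean insert of an already placed
  gene, which produces gene islands. The non-syntenic flag is Bernoulli
  with probability interpolated along `nonsyntenic_gradient` (default
  0.45→0.75, i.e. ~60% non-syntenic overall, rising distally). Syntenic
  genes receive order-preserving ortholog indices in three reference
  genomes, on a proximal reference chromosome below 47% of the arm and a
  distal one above it (the synteny-breakpoint structure seen in grass
  comparative maps); non-syntenic genes point to arbitrary reference
  locations with probability 0.7 per genome.
* **Deletion lines** are terminal: a line with breakpoint `b` retains
  `[0, b·length)`, so marker presence is simply `pos < b·length`. Eight
  breakpoints (0.23 … 0.89) define nine bins.
* **Recombination** is piecewise constant: 0.05 cM/Mb over the proximal
  63% of the arm, 0.20 over the next 21%, 1.0 over the distal 16%,
  integrating to ~124.9 cM on a 535 Mb arm.
* **Determinism.** One integer seed; each operation uses its own child
  stream `default_rng([seed, stream_id])`, so outputs are reproducible
  and independent of call order.

What the generator does **not** emulate: sequence content (no FASTA, no
transposable elements), partial digests or electropherogram artefacts
beyond the three-parameter noise model, correlated marker failure, or
chimeric clones (tests construct those explicitly). Passing tests
therefore show the algorithms are correct under the stated statistical
structure, not that they are robust to every artefact of real gels.

## Fingerprint assembly

`match_bands` computes the maximum one-to-one matching between two sorted
band lists with tolerance `t` by a two-pointer sweep (optimal for points
on a line; the hot pairwise loop is numba-compiled when numba is
available, with a pure-Python fallback). `sulston_score` is the standard
binomial tail with per-band match probability `p = 2 t n_H / G`; scores
are carried in log10 throughout (an exact log-sum-exp evaluation replaces
the scipy tail where it underflows), and edge "strength" is a total order
(log-score, then shared bands, then clone ids) so equal scores never
deadlock the reduction.

The pipeline: components at the subnet cut-off (1e-25) are candidate
contigs; a transitive-reduction skeleton drops edge (a,c) when a common
neighbour b is strictly stronger to both and shares at least as many
bands with each; width = branch nodes (degree > 2) + independent cycles.
Width-0 components whose skeleton is a simple path are validated, ordered
from the lexicographically smaller endpoint, and given CB coordinates
(each clone advances by its bands unmatched to its predecessor).
Deviations are handled in order: pendant skeleton leaves hanging off
branch nodes are **buried** into their host clone (they are redundant,
typically nested, inserts; they stay in the contig at the host's CB
coordinate, as FPC buries clones); a single clone explaining the
non-linearity is eliminated as a Q clone; otherwise Q clones are removed
iteratively (the clone whose deletion most reduces total width, with a
budget of `q_fraction` of the component) and, for components that still
fail, the strict cut-off (1e-30) re-splits them, after which Q
elimination may run once more. Linear components exceeding `max_contig`
are split into nearly equal consecutive chunks. Whatever remains is
reported as an unvalidated contig, so every input clone lands in exactly
one contig or the unassembled set.

Numerical/performance notes: all pairwise scores are computed once per
assembly (O(n²) band sweeps, vectorised binomial tails); single-removal
searches are capped at 25 candidate clones drawn from skeleton defects.
The assembly is tuned for the 3–6x redundancy regime used in the tests;
at full 15x redundancy the Q-budget becomes the limiting factor and a
larger `q_fraction` would be needed.

MTP selection is greedy left-to-right on CB coordinates (largest
extension whose overlap lies in `[min_overlap, max_overlap]` with at
least `min_shared_bands` shared bands; if none qualifies the
largest-overlap extender is taken and a gap-risk warning recorded).
`assembly_stats` converts CB spans to kb with `kb_per_cb`, by default
1.2 ≈ mean insert / mean band count; N50/L50 follow the cumulative-sum
definition. A classic high-stringency preset (`fpc_preset`: cut-offs
1e-75→1e-45, gel 56,000, from-end 55 kept as an inert field) is provided
for comparison; the linear-topology procedure is the default.

## Pooling and deconvolution

Clones fill 16x24 plates plate-major, row-major; plate pools plus
row/column pools spanning all plates (63 pools for a 23-plate MTP).
Simulated screens mark a pool positive iff it holds a clone covering the
marker, then flip calls at the given false-negative/-positive rates.

DSMP deconvolution ranks explanations: a single clone; a run of 2–4
overlapping clones in one contig (case A — generalised from a pair
because a dense MTP often leaves a marker covered by three clones); two
clones of different contigs with fingerprints matching at 1e-25 (case B,
also a contig-merge hint); an overlapping pair plus a matching third
(case C); two matching pairs (case D). Unassembled clones are treated as
singleton contigs so the cross-contig cases can reach them. Two
extensions keep the ladder sound and complete on clean data: a unique
candidate pair (or overlapping-pair-plus-third triple) that explains the
positive pattern exactly is accepted even without a fingerprint match
(markers at junctions between abutting contigs); the classic 2x2
row/column ambiguity is broken only by decisive fingerprint evidence
(pairs: a mutual overlap at the net cut-off; triples: contig-terminus
consistency, then a 10^3 margin in support), otherwise the marker stays
unresolved. If no exact explanation exists the ladder is retried
tolerating up to 2 unexplained positive pools, with candidates allowed to
miss one of their three pools — but never when exact explanations exist
and merely disagree.

Array positivity: the mean + k·SD coefficient ladders per pool dimension
(plate 2.7→2.0, row 2.8→2.1, column 3.0→2.2) are walked from strict to
lenient per probe, stopping at the first k that yields a positive;
zero-SD probes are skipped. Multi-probe junction markers are called per
pool after background subtraction (median of empty spots), log2,
lowess trend removal against the **other** pools' median intensity (using
the pool's own signal as reference would smooth genuine positives away),
median centering and SD scaling; a marker needs >= 75% of its probes
above mean + 2 SD and a one-sided one-sample t-test p < 0.05. The
Elephant-style plate-pool scorer uses weights (+5, −2, −1) — the
published description fixes only the threshold of 13, so explicit weights
make the threshold meaningful — and assigns a marker only when exactly
one contig segment (contigs split at branching clones) clears it.

## Map integration

Bin assignment from deletion patterns requires monotone absence→presence;
anything else is ambiguous. Contigs inherit their markers' bins, 0.5 to
each of two consecutive bins, excluded with a warning on non-consecutive
conflicts. Corrected bin size = anchored Mb / anchored fraction; bin
genetic spans are max − min framework cM over the bin's markers (how the
published analysis delimited spans is not stated; this is the natural
reading), with adjacent bins mergeable where the genetic map cannot
separate them. Kosambi conversion and interval-ratio projection of
neighbour maps are closed-form; non-collinear shared loci are dropped by
a longest-nondecreasing-subsequence filter before projection. Genetic map
construction itself (grouping, multipoint ordering) is out of scope:
orders are accepted as inputs.

## Synteny ordering

Hit filters are inclusive thresholds (ortholog 35%/40 aa with best hit
per query and genome; membership 98%/57 bp; order-comparison 90%/100 bp;
ancestral 35%/70% coverage). Blocks are longest monotone subsequences of
reference indices (step <= `max_gap` = 10) in the provisional gene order,
extracted longest-first per reference chromosome — an interloper inside a
run is skipped, not chain-breaking. Within bins, contigs sort by median
reference index under the bin's majority reference genome; a contig whose
block-mates mostly lie in another bin is flagged discrepant (the
translocation signal) and left unordered. Gene positions are mean CB
coordinates of their clones; ties on identical clone sets break by
reference index, then by a seeded shuffle (confidence low, source
"random"). The zipper slides 500 kb windows (shift 100 kb) over reference
coordinates, keeps windows above mean + 1 SD hit density, anchors genes
with bidirectional marker hits at the marker's cM and interpolates the
rest in reference order. Order concordance is the longest-common-
subsequence fraction over shared genes — it is 1.0 for identical orders
and (n−1)/n for one adjacent swap, which is what "exact same order"
percentages need to behave sensibly; block orientations compare by rank-
correlation sign.

## Gene-space statistics

Bin tables report genes/Mb at 2 decimals; correlations are Pearson with
the two-sided t-transform p (n−2 df), with the bin's fraction midpoint as
the distance variable (the published analysis does not state its
x-values). Islands are connected components (>= 2 genes) of the graph
joining genes whose clone sets intersect or contain overlapping clones;
the overlap relation defaults to assembly-derived adjacency, with
truth intervals used only as test oracles. The resampling null draws the
observed number of genes onto distinct clones ("without replacement" read
as one gene per distinct clone; the alternative reading is available by
resampling with a different overlap graph), recomputes the in-island
fraction per draw (vectorised as a sparse adjacency product), and
compares observed vs expected in-island/isolated counts by a 1-df
chi-squared; p-values below 1e-15 print as "<1e-15".

## Problem sizes used in tests and the acceptance script

Simulation-backed checks run at reduced scale chosen to keep each stage
in its intended operating regime: assembly truth recovery on a 50 Mb arm
with 2,000 clones (~5x redundancy, the regime where subnets resolve into
contigs with gaps between them); deconvolution on a 20 Mb arm, 800
clones, 500 markers; the island null at one tenth of the full arm with
1,000 draws; and the recombination-profile recovery at the full 535 Mb
scale using contigs built from truth clone overlaps at ~1.5x tiling
coverage — the anchoring arithmetic needs many contigs per bin to
average anchoring fluctuations, which the fingerprint route cannot
provide at a tractable clone count, and the fingerprint route is
validated separately. Exhaustive oracles (orderings, island
enumerations, brute-force matchings) run at sizes where enumeration is
exact (<= 9 clones, C(12,5) placements).

## Known limitations

* The skeleton width is an operational proxy for linear topology; a bare
  cycle scores width 1 and passes validation.
* CB coordinates are asymmetric under path reversal when band counts
  differ (each step counts the successor's unmatched bands); distances
  are exactly preserved only for equal band counts.
* The Q-clone budget (10%) under-serves redundancy above ~8x, where most
  clones are buried or removed and validated coverage drops.
* The 0.5/0.5 straddling rule and the global anchored-fraction correction
  are faithful to the published procedure but noisy when a bin holds only
  a handful of contigs.
* Elephant's true scoring function is unpublished; the (+5, −2, −1)
  weights are this package's explicit, configurable stand-in.
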