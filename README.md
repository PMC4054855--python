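# physmap

Tools for building and exploiting a high-density BAC physical map of a
plant chromosome arm, modelled on the workflow used for wheat chromosome
arm 1BL: restriction-band fingerprint assembly of clones into linear
contigs, minimal-tiling-path (MTP) selection, three-dimensional
pooled-library marker screening with deconvolution back to individual
clones, anchoring of markers and contigs into terminal-deletion bins,
physical/genetic distance profiling, synteny-based ordering against
reference grass genomes, and gene-space statistics (density gradients,
gene islands, a resampling null). A synthetic ground-truth generator
reproduces the statistical structure of the real data — clone library,
noisy fingerprints, deletion breakpoints, recombination zones, ortholog
structure — so every stage can be tested end to end without any external
data.

## The model in brief

**Clone overlap.** Each BAC clone is reduced to its fingerprint, the
multiset of restriction-fragment sizes (50–500 bp, sized to ~0.01 bp and
handled in centi-bp mobility units). Two fingerprints with band counts
`n_L <= n_H` sharing `m` bands within tolerance `t` overlap with Sulston
score

    S = sum_{k=m}^{n_L} C(n_L, k) p^k (1-p)^(n_L-k),   p = 2 t n_H / G

with gel length `G`; low `S` means the shared bands are unlikely by
chance. Assembly proceeds LTC-style: a net of significant overlaps
(`S <= 1e-15`), subnets at `1e-25` as contig candidates, validation by
size (5–999 clones) and by the linearity of a transitive-reduction
skeleton ("net width <= 1"), elimination of questionable (Q) clones, and
a re-split of recalcitrant components at `1e-30`. Validated contigs get
consensus-band (CB) coordinates, from which an MTP is chosen greedily
(overlaps within [30, 250] CB units, >= 12 shared bands).

**Deconvolution.** MTP clones are pooled by plate, row and column; a
marker's positive pools are inverted to clones through a ladder of
explanations (one clone; a run of overlapping clones in one contig; pairs
or pairs-plus-matches across contigs linked by fingerprint matches at
`1e-25`), with a bounded noise tolerance for false pool calls. Screens of
whole-library plate pools are resolved by an Elephant-style segment
scorer (weights +5/−2/−1, threshold 13).

**Anchoring and profiling.** Terminal deletion lines truncate the arm at
fixed fractions; a marker's presence pattern across the lines places it
in one of nine deletion bins, contigs inherit their markers' bins (0.5
weight to each of two consecutive bins), bin physical sizes are the
anchored contig sums corrected by the anchored fraction, and genetic
spans over bins give a cM/Mb recombination profile. Recombination
fractions convert to map distances by Kosambi,
`d = 25 ln((1+2r)/(1-2r))`.

**Gene space.** Orthology hits filtered at >= 35% identity over >= 40 aa
chain into collinear blocks (monotone reference indices, gaps <= 10),
which classify genes as syntenic or not, order contigs within bins, and
break ties in the CB-based virtual gene order. Gene islands are connected
components of genes on the same or overlapping clones; their observed
fraction is tested against 10,000 re-placements of the genes on randomly
drawn clones with a 1-df chi-squared statistic.

## Worked example

```python
import physmap as pm

cfg = pm.SimulationConfig(chromosome_length=5_000, n_clones=150,
                          n_genes=60, n_markers={"ISBP": 40, "SSR": 8},
                          band_noise=pm.BandNoise(0, 0, 0), seed=11)
chrom  = pm.simulate_chromosome(cfg)
clones = pm.simulate_bac_library(chrom, cfg)
fps    = pm.simulate_fingerprints(clones, chrom, cfg)
print(f"coverage {pm.library_coverage(clones, chrom.length):.1f}x")

result    = pm.assemble_contigs(fps)
validated = [c for c in result.contigs if c.validated]
mtp, _    = pm.select_mtp(validated, fps)
stats     = pm.assembly_stats(validated, cfg.chromosome_length,
                              kb_per_cb=1.2)
print(f"{len(validated)} validated contigs, N50 {stats.n50_kb:.0f} kb, "
      f"L50 {stats.l50}, MTP of {len(mtp)} clones")
```

prints

```
coverage 3.8x
7 validated contigs, N50 848 kb, L50 3, MTP of 60 clones
```

— a 5 Mb arm sampled at 3.8x clone redundancy assembles into 7 validated
linear contigs whose N50 (the contig size such that contigs at least that
large cover half the assembly) is 848 kb, with 60 clones sufficing as a
tiling path for downstream screening. The same objects feed the pooling,
anchoring, synteny and gene-space modules; `physmap --help` exposes the
file-based pipeline (`simulate`, `assemble`, `mtp`, `stats`,
`anchor ...`, `synteny ...`, `islands`).

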