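"""Synteny-based ordering and virtual gene orders.

Homology hits against reference grass genomes are filtered at fixed
identity/length profiles; runs of genes whose reference indices are
collinear form synteny blocks; blocks order contigs within deletion bins
and break ties between genes sharing clones; a zipper-style order anchors
reference-genome synteny to a genetic marker backbone; and two virtual
orders are compared by their longest common subsequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: hit-filter profiles: (min percent identity, length column, min length)
FILTER_PROFILES = {
    "ortholog_35_40aa": (35.0, "aln_len", 40.0),
    "membership_98_57bp": (98.0, "aln_len", 57.0),
    "common_90_100bp": (90.0, "aln_len", 100.0),
    "ancestral_35_70pct": (35.0, "coverage", 0.70),
}


@dataclass
class SyntenyBlock:
    ref_genome: str
    ref_chr: str
    genes: list  # ordered member gene ids (provisional chromosome order)
    ref_indices: list
    orientation: str  # 'same' | 'inverted'

    def __len__(self):
        return len(self.genes)


@dataclass
class VirtualGeneOrder:
    genes: list  # ordered gene ids
    confidence: dict  # gene -> 'high' | 'low'
    source: dict  # gene -> 'bin' | 'synteny' | 'CB' | 'random'

    def __len__(self):
        return len(self.genes)


@dataclass
class ZipperMap:
    loci: list  # (locus id, cM, anchor type)
    #: anchor types: marker_backbone | bidirectional_hit | reference_interpolated

    def gene_order(self):
        return [l[0] for l in self.loci]


# ---------------------------------------------------------------------------
# hit filtering

def filter_hits(hits: pd.DataFrame, profile: str) -> pd.DataFrame:
    """Drop hits failing the profile's identity/length floor (inclusive
    bounds). The ortholog profile additionally keeps only the best hit per
    (query, reference genome), by identity then alignment length."""
    if profile not in FILTER_PROFILES:
        raise ValueError(f"unknown filter profile {profile!r}; "
                         f"choose from {sorted(FILTER_PROFILES)}")
    min_id, len_col, min_len = FILTER_PROFILES[profile]
    kept = hits[(hits["pct_id"] >= min_id) & (hits[len_col] >= min_len)]
    if profile == "ortholog_35_40aa" and len(kept):
        kept = (kept.sort_values(["pct_id", "aln_len"], ascending=False)
                .groupby(["query", "ref_genome"], as_index=False, sort=False)
                .head(1))
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# collinear blocks

def detect_blocks(hits: pd.DataFrame, gene_order, min_block: int = 3,
                  max_gap: int = 10) -> list:
    """Collinear blocks per reference genome and chromosome.

    Genes are taken in their provisional chromosome order; a block is a
    maximal monotone run of reference indices with steps of at most
    ``max_gap`` (genes breaking the run are skipped, not chain-breaking).
    Blocks are extracted longest-first from a longest-monotone-subsequence
    dynamic programme; runs shorter than ``min_block`` are discarded.
    """
    rank = {g: i for i, g in enumerate(gene_order)}
    blocks = []
    best = {}
    for (genome, chrom), grp in hits.groupby(["ref_genome", "ref_chr"]):
        grp = grp[grp["query"].isin(rank)]
        grp = grp.sort_values("query", key=lambda s: s.map(rank))
        genes = list(grp["query"])
        idx = list(grp["ref_index"].astype(int))
        for member_pos in _extract_chains(idx, min_block, max_gap):
            members = [genes[i] for i in member_pos]
            indices = [idx[i] for i in member_pos]
            orientation = "same" if indices[-1] >= indices[0] else "inverted"
            blocks.append(SyntenyBlock(ref_genome=genome, ref_chr=chrom,
                                       genes=members, ref_indices=indices,
                                       orientation=orientation))
    blocks.sort(key=lambda b: (-len(b), b.ref_genome, b.ref_chr))
    return blocks


def _longest_chain(idx, direction, max_gap):
    """Longest strictly monotone subsequence with index steps <= max_gap."""
    n = len(idx)
    length = [1] * n
    parent = [-1] * n
    for i in range(n):
        for j in range(i):
            step = direction * (idx[i] - idx[j])
            if 1 <= step <= max_gap and length[j] + 1 > length[i]:
                length[i] = length[j] + 1
                parent[i] = j
    if not n:
        return []
    end = int(np.argmax(length))
    chain = []
    while end >= 0:
        chain.append(end)
        end = parent[end]
    return list(reversed(chain))


def _extract_chains(idx, min_block, max_gap):
    positions = list(range(len(idx)))
    out = []
    while True:
        sub_idx = [idx[p] for p in positions]
        best_chain = []
        for direction in (1, -1):
            chain = _longest_chain(sub_idx, direction, max_gap)
            if len(chain) > len(best_chain):
                best_chain = chain
        if len(best_chain) < min_block:
            break
        out.append([positions[i] for i in best_chain])
        taken = {positions[i] for i in best_chain}
        positions = [p for p in positions if p not in taken]
    return out


def classify_synteny(genes, blocks) -> dict:
    """gene id -> 'syntenic' (member of a block in any reference genome)
    or 'non_syntenic'."""
    in_block = set()
    for b in blocks:
        in_block.update(b.genes)
    return {g: ("syntenic" if g in in_block else "non_syntenic")
            for g in genes}


# ---------------------------------------------------------------------------
# contig and gene ordering

def order_contigs(bin_assignment, blocks, gene_contigs: dict):
    """Order contigs within bins by the reference order of their block
    genes.

    Bins run centromere -> telomere. Within a bin the reference genome is
    chosen by majority vote of block memberships; contigs with syntenic
    genes sort by the median reference index of those genes. A contig
    whose block-mates mostly sit in a different bin is flagged discrepant
    (a rearrangement signal) and excluded from the order. Contigs without
    syntenic genes stay in their bin, unordered.

    Returns (ordered entries, discrepant contig ids); each entry is
    (contig id, bin name, median reference index or None).
    """
    bin_rank = {b.name: i for i, b in enumerate(bin_assignment.bins)}
    contig_bin = {}
    for bin_name, weights in bin_assignment.contig_weights.items():
        for contig in weights:
            cur = contig_bin.get(contig)
            if cur is None or bin_rank[bin_name] < bin_rank[cur]:
                contig_bin[contig] = bin_name

    gene_block = {}
    for b in blocks:
        for g in b.genes:
            gene_block.setdefault(g, []).append(b)

    # per-bin majority reference genome
    votes: dict = {}
    for gene, blist in gene_block.items():
        contig = gene_contigs.get(gene)
        bin_name = contig_bin.get(contig)
        if bin_name is None:
            continue
        for b in blist:
            votes.setdefault(bin_name, {})
            votes[bin_name][b.ref_genome] = \
                votes[bin_name].get(b.ref_genome, 0) + 1
    bin_genome = {bn: max(sorted(v), key=lambda g: v[g])
                  for bn, v in votes.items()}

    discrepant = []
    entries = []
    contigs_by_bin: dict = {}
    for contig, bin_name in contig_bin.items():
        contigs_by_bin.setdefault(bin_name, []).append(contig)
    for bin_name in sorted(contigs_by_bin, key=lambda bn: bin_rank[bn]):
        genome = bin_genome.get(bin_name)
        placed = []
        unordered = []
        for contig in sorted(contigs_by_bin[bin_name]):
            indices = []
            mate_bins: list = []
            for gene, cg in gene_contigs.items():
                if cg != contig or gene not in gene_block:
                    continue
                for b in gene_block[gene]:
                    if b.ref_genome != genome:
                        continue
                    indices.append(b.ref_indices[b.genes.index(gene)])
                    for mate in b.genes:
                        mate_contig = gene_contigs.get(mate)
                        if mate_contig is not None and mate_contig != contig:
                            mb = contig_bin.get(mate_contig)
                            if mb is not None:
                                mate_bins.append(mb)
            if not indices:
                unordered.append(contig)
                continue
            if mate_bins:
                disagree = sum(1 for mb in mate_bins if mb != bin_name)
                if disagree > len(mate_bins) / 2:
                    logger.warning(
                        "contig %s: block mates lie in other bins; flagged "
                        "discrepant", contig)
                    discrepant.append(contig)
                    continue
            placed.append((contig, float(np.median(indices))))
        placed.sort(key=lambda t: (t[1], t[0]))
        entries.extend((c, bin_name, pos) for c, pos in placed)
        entries.extend((c, bin_name, None) for c in unordered)
    return entries, discrepant


def order_genes(ordered_contigs, contig_cb: dict, gene_clones: dict,
                blocks, seed: int = 0) -> VirtualGeneOrder:
    """Linear gene order from contig order and consensus-band coordinates.

    A gene sits at the mean CB coordinate of its clones; genes tied on an
    identical clone set are ordered by reference index when a block
    provides one, otherwise by a seeded random draw. Confidence is high
    for genes with an unambiguous relative position or synteny support.
    """
    rng = np.random.default_rng([seed, 97])
    gene_ref_index = {}
    for b in blocks:
        for g, i in zip(b.genes, b.ref_indices):
            gene_ref_index.setdefault(g, i)

    contig_rank = {}
    for rank, entry in enumerate(ordered_contigs):
        contig_id = entry[0] if isinstance(entry, tuple) else entry
        contig_rank[contig_id] = rank

    clones_contig = {}
    for contig_id, cb in contig_cb.items():
        for clone in cb:
            clones_contig[clone] = contig_id

    placed = []
    for gene, clones in gene_clones.items():
        clones = [c for c in clones if c in clones_contig]
        if not clones:
            logger.info("gene %s has no clone in an ordered contig; excluded",
                        gene)
            continue
        contig_id = clones_contig[clones[0]]
        if contig_id not in contig_rank:
            continue
        cb = contig_cb[contig_id]
        pos = float(np.mean([cb[c] for c in clones]))
        placed.append((contig_rank[contig_id], pos, frozenset(clones), gene))

    groups: dict = {}
    for rank, pos, cset, gene in placed:
        groups.setdefault((rank, pos, cset), []).append(gene)

    order = []
    confidence = {}
    source = {}
    for key in sorted(groups, key=lambda k: (k[0], k[1], sorted(k[2]))):
        genes = groups[key]
        if len(genes) == 1:
            g = genes[0]
            order.append(g)
            confidence[g] = "high"
            source[g] = "CB"
            continue
        with_idx = [g for g in genes if g in gene_ref_index]
        without = [g for g in genes if g not in gene_ref_index]
        with_idx.sort(key=lambda g: (gene_ref_index[g], g))
        rng.shuffle(without)
        for g in with_idx:
            order.append(g)
            confidence[g] = "high"
            source[g] = "synteny"
        for g in without:
            order.append(g)
            confidence[g] = "low"
            source[g] = "random"
    return VirtualGeneOrder(genes=order, confidence=confidence, source=source)


# ---------------------------------------------------------------------------
# zipper

def build_zipper(backbone, gene_hits: pd.DataFrame, anchors: dict,
                 window_kb: float = 500.0, shift_kb: float = 100.0,
                 density_sds: float = 1.0) -> ZipperMap:
    """Marker-backbone virtual order from reference-genome synteny.

    ``backbone``: [(marker id, cM)], >= 2 markers. ``gene_hits``: one row
    per gene with columns gene, ref_chr, ref_pos_kb. ``anchors``: gene ->
    backbone marker for bidirectional best hits. Windows of ``window_kb``
    slid by ``shift_kb`` over each reference chromosome; windows with hit
    density >= mean + density_sds*SD define syntenic regions. Anchored
    genes take their marker's cM; other syntenic-region genes interpolate
    between flanking anchored loci in reference order.
    """
    if len(backbone) < 2:
        raise ValueError("backbone needs at least 2 markers")
    marker_cm = dict(backbone)
    loci = [(m, cm, "marker_backbone") for m, cm in backbone]

    syntenic_genes = []
    for chrom, grp in gene_hits.groupby("ref_chr"):
        pos = grp["ref_pos_kb"].to_numpy(dtype=float)
        lo, hi = pos.min(), pos.max()
        starts = np.arange(lo, max(hi - window_kb, lo) + shift_kb, shift_kb)
        counts = np.array([((pos >= s) & (pos < s + window_kb)).sum()
                           for s in starts])
        thr = counts.mean() + density_sds * counts.std()
        regions = _merge_windows(starts[counts >= thr], window_kb)
        sel = grp[[any(s <= p < e for s, e in regions)
                   for p in pos]].sort_values("ref_pos_kb")
        syntenic_genes.extend(zip(sel["gene"], sel["ref_pos_kb"]))
    if not syntenic_genes:
        logger.warning("no syntenic window found; zipper is empty")
        return ZipperMap(loci=[])

    anchored = []
    unanchored = []
    for gene, ref_pos in syntenic_genes:
        marker = anchors.get(gene)
        if marker is not None and marker in marker_cm:
            anchored.append((gene, ref_pos, marker_cm[marker]))
        else:
            unanchored.append((gene, ref_pos))
    anchored.sort(key=lambda t: t[1])
    for gene, _pos, cm in anchored:
        loci.append((gene, cm, "bidirectional_hit"))

    if anchored:
        a_pos = [p for _g, p, _c in anchored]
        a_cm = [c for _g, _p, c in anchored]
        for gene, ref_pos in sorted(unanchored, key=lambda t: t[1]):
            i = int(np.searchsorted(a_pos, ref_pos)) - 1
            i = min(max(i, 0), len(anchored) - 2) if len(anchored) > 1 else 0
            if len(anchored) == 1:
                cm = a_cm[0]
            else:
                pa, pb = a_pos[i], a_pos[i + 1]
                ca, cb = a_cm[i], a_cm[i + 1]
                cm = ca if pb == pa else ca + (cb - ca) * (ref_pos - pa) / (pb - pa)
            loci.append((gene, cm, "reference_interpolated"))
    loci.sort(key=lambda t: (t[1], t[0]))
    return ZipperMap(loci=loci)


def _merge_windows(starts, window_kb):
    regions = []
    for s in starts:
        if regions and s <= regions[-1][1]:
            regions[-1] = (regions[-1][0], s + window_kb)
        else:
            regions.append((s, s + window_kb))
    return regions


# ---------------------------------------------------------------------------
# order comparison

def compare_orders(order_a, order_b, blocks=None) -> dict:
    """Concordance of two virtual gene orders.

    The same-order fraction is |longest common subsequence of the two
    orders restricted to common genes| / |common genes|. With blocks
    given, each block also gets an orientation agreement sign (rank
    correlation of its members' positions in the two orders).
    """
    genes_a = order_a.genes if isinstance(order_a, VirtualGeneOrder) \
        else list(order_a)
    genes_b = order_b.gene_order() if isinstance(order_b, ZipperMap) \
        else (order_b.genes if isinstance(order_b, VirtualGeneOrder)
              else list(order_b))
    common = set(genes_a) & set(genes_b)
    if len(common) < 2:
        raise ValueError("need >= 2 common genes to compare orders")
    a_seq = [g for g in genes_a if g in common]
    b_rank = {g: i for i, g in enumerate(g for g in genes_b if g in common)}
    seq = [b_rank[g] for g in a_seq]
    lcs = _longest_increasing_length(seq)
    report = {
        "n_common": len(common),
        "lcs": lcs,
        "same_order_fraction": lcs / len(common),
        "block_orientation": {},
    }
    if blocks:
        a_rank = {g: i for i, g in enumerate(a_seq)}
        for k, b in enumerate(blocks):
            members = [g for g in b.genes if g in common]
            if len(members) < 2:
                continue
            xs = [a_rank[g] for g in members]
            ys = [b_rank[g] for g in members]
            rho = np.corrcoef(xs, ys)[0, 1]
            report["block_orientation"][f"block{k}"] = (
                "agree" if rho >= 0 else "inverted")
    return report


def _longest_increasing_length(seq):
    import bisect

    tails: list = []
    for v in seq:
        i = bisect.bisect_left(tails, v)
        if i == len(tails):
            tails.append(v)
        else:
            tails[i] = v
    return len(tails)


# ---------------------------------------------------------------------------
# ancestral duplication retention

@dataclass
class RetentionResult:
    counted: dict  # arm -> set of reference gene ids
    excluded: list  # reference genes hitting too many arms
    per_arm: dict = field(init=False)

    def __post_init__(self):
        self.per_arm = {arm: len(s) for arm, s in self.counted.items()}

    def group_count(self, arms) -> int:
        union = set()
        for arm in arms:
            union |= self.counted.get(arm, set())
        return len(union)

    def shared(self, arm_x, arm_y) -> int:
        return len(self.counted.get(arm_x, set())
                   & self.counted.get(arm_y, set()))

    def pair_retention(self, pairs, arm_x, arm_y) -> int:
        """Duplicated reference-gene pairs with one member retained on each
        target arm."""
        cx = self.counted.get(arm_x, set())
        cy = self.counted.get(arm_y, set())
        return sum(1 for a, b in pairs
                   if (a in cx and b in cy) or (b in cx and a in cy))


def ancestral_retention(hits: pd.DataFrame, max_arms: int = 12,
                        min_identity: float = 35.0,
                        min_coverage: float = 0.70) -> RetentionResult:
    """Count ancestral reference genes retained per chromosome arm.

    ``hits``: one row per (ref_gene, arm) with cumulative pct_id/coverage.
    An arm counts a reference gene iff identity >= min_identity and
    cumulative coverage >= min_coverage (inclusive). Reference genes
    qualifying on more than ``max_arms`` arms are treated as members of
    large multigene families and excluded.
    """
    ok = hits[(hits["pct_id"] >= min_identity)
              & (hits["coverage"] >= min_coverage)]
    arms_per_gene = ok.groupby("ref_gene")["arm"].nunique()
    excluded = sorted(arms_per_gene[arms_per_gene > max_arms].index)
    ok = ok[~ok["ref_gene"].isin(excluded)]
    counted = {arm: set(grp["ref_gene"]) for arm, grp in ok.groupby("arm")}
    return RetentionResult(counted=counted, excluded=excluded)
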