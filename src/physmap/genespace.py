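"""Gene-space statistics: density gradients, gene islands, resampling null.

Gene islands are groups of two or more genes carried by the same or
overlapping clones. Whether the observed fraction of genes in islands
exceeds chance is judged against a resampling null: genes are repeatedly
re-placed on clones drawn without replacement, islands are re-detected,
and the observed in-island/isolated split is tested against the null
expectation with a 1-df chi-squared statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats, sparse

logger = logging.getLogger(__name__)


@dataclass
class GeneIsland:
    genes: list  # >= 2 member gene ids
    clones: list  # supporting clone ids

    def __len__(self):
        return len(self.genes)


@dataclass
class ResamplingNull:
    n_draws: int
    fractions: np.ndarray  # per-draw in-island gene fraction
    mean: float
    sd: float
    chi2: float
    p_value: float
    seed: int

    def p_label(self, floor: float = 1e-15) -> str:
        return f"<{floor:g}" if self.p_value < floor else f"{self.p_value:g}"


# ---------------------------------------------------------------------------
# summary table

def bin_stats_table(assignment, gene_bins: dict, classifications: dict,
                    island_genes=frozenset()) -> pd.DataFrame:
    """Per-bin summary: markers, fractional contig counts, contig kb,
    genes, gene density (genes per Mb of anchored contigs), non-syntenic
    genes and genes in islands, plus a totals row."""
    island_genes = set(island_genes)
    rows = []
    for b in assignment.bins:
        genes = [g for g, bn in gene_bins.items() if bn == b.name]
        kb = assignment.cumulative_kb.get(b.name, 0.0)
        mb = kb / 1000.0
        n_genes = len(genes)
        rows.append({
            "bin": b.name,
            "markers_assigned": len(assignment.markers.get(b.name, [])),
            "contigs": sum(assignment.contig_weights.get(b.name, {})
                           .values()),
            "contig_mb": round(mb, 2),
            "genes": n_genes,
            "gene_density": round(n_genes / mb, 2) if mb else 0.0,
            "non_syntenic": sum(
                1 for g in genes
                if classifications.get(g) == "non_syntenic"),
            "genes_in_islands": sum(1 for g in genes if g in island_genes),
        })
    df = pd.DataFrame(rows)
    total_mb = df["contig_mb"].sum()
    total_genes = int(df["genes"].sum())
    totals = {
        "bin": "Total",
        "markers_assigned": int(df["markers_assigned"].sum()),
        "contigs": float(df["contigs"].sum()),
        "contig_mb": round(total_mb, 2),
        "genes": total_genes,
        "gene_density": round(total_genes / total_mb, 2) if total_mb else 0.0,
        "non_syntenic": int(df["non_syntenic"].sum()),
        "genes_in_islands": int(df["genes_in_islands"].sum()),
    }
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


# ---------------------------------------------------------------------------
# correlations

def pearson_with_p(x, y):
    """Sample Pearson r with a two-sided p-value from the t transform
    (n-2 df). Raises on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_report(stats_table: pd.DataFrame, bin_midpoints: dict
                       ) -> pd.DataFrame:
    """Five standard correlations over bins (totals row excluded):
    gene density vs distance from centromere, and non-syntenic / syntenic
    / island / isolated gene densities vs total density. Rows failing
    (zero variance) carry NaN and an error note."""
    df = stats_table[stats_table["bin"] != "Total"].copy()
    if len(df) < 3:
        raise ValueError("need at least 3 bins")
    df["distance"] = df["bin"].map(bin_midpoints)
    mb = df["contig_mb"].replace(0, np.nan)
    density = df["genes"] / mb
    rows = [
        ("density_vs_distance", density, df["distance"]),
        ("nonsyntenic_density_vs_density", df["non_syntenic"] / mb, density),
        ("syntenic_density_vs_density",
         (df["genes"] - df["non_syntenic"]) / mb, density),
        ("island_density_vs_density", df["genes_in_islands"] / mb, density),
        ("isolated_density_vs_density",
         (df["genes"] - df["genes_in_islands"]) / mb, density),
    ]
    out = []
    for name, x, y in rows:
        mask = x.notna() & y.notna()
        try:
            r, p = pearson_with_p(x[mask], y[mask])
            out.append({"correlation": name, "r": r, "p": p, "note": ""})
        except ValueError as err:
            out.append({"correlation": name, "r": np.nan, "p": np.nan,
                        "note": str(err)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# gene islands

def clone_overlap_graph(clones) -> nx.Graph:
    """Overlap relation from truth intervals (oracle use): edge between
    clones whose [start, end) intervals intersect."""
    g = nx.Graph()
    items = sorted(clones, key=lambda c: c.start)
    g.add_nodes_from(c.id for c in items)
    active = []
    for c in items:
        active = [a for a in active if a.end > c.start]
        for a in active:
            g.add_edge(a.id, c.id)
        active.append(c)
    return g


def contig_adjacency_graph(contigs, fingerprint_lengths=None) -> nx.Graph:
    """Overlap relation from the assembly: clones adjacent in a contig's
    CB order, or with intersecting CB intervals when band counts are
    supplied, are connected."""
    g = nx.Graph()
    for contig in contigs:
        g.add_nodes_from(contig.clones)
        for a, b in zip(contig.clones, contig.clones[1:]):
            g.add_edge(a, b)
        if fingerprint_lengths:
            cb = contig.cb
            spans = [(c, cb[c], cb[c] + fingerprint_lengths.get(c, 0))
                     for c in contig.clones]
            spans.sort(key=lambda t: t[1])
            for i, (a, a_lo, a_hi) in enumerate(spans):
                for b, b_lo, _b_hi in spans[i + 1:]:
                    if b_lo >= a_hi:
                        break
                    g.add_edge(a, b)
    return g


def detect_islands(gene_clones: dict, overlap: nx.Graph):
    """Gene islands: connected components (size >= 2) of the graph joining
    genes whose clone sets intersect or contain overlapping clones.

    Returns (islands, isolated gene ids).
    """
    gg = nx.Graph()
    genes = []
    for gene, clones in gene_clones.items():
        clones = [c for c in clones if c in overlap]
        if not clones:
            logger.info("gene %s has no clone; excluded from island "
                        "detection", gene)
            continue
        genes.append((gene, set(clones)))
        gg.add_node(gene)
    # index genes by clone and by clone neighbourhood
    by_clone: dict = {}
    for gene, clones in genes:
        reach = set(clones)
        for c in clones:
            reach.update(overlap[c])
        for c in reach:
            by_clone.setdefault(c, []).append(gene)
    for gene, clones in genes:
        for c in clones:
            for other in by_clone.get(c, ()):
                if other != gene:
                    gg.add_edge(gene, other)
    islands = []
    isolated = []
    clone_sets = dict(genes)
    for comp in nx.connected_components(gg):
        if len(comp) >= 2:
            clones = sorted(set().union(*(clone_sets[g] for g in comp)))
            islands.append(GeneIsland(genes=sorted(comp), clones=clones))
        else:
            isolated.extend(comp)
    islands.sort(key=lambda isl: isl.genes)
    return islands, sorted(isolated)


def island_size_distribution(islands) -> dict:
    sizes = np.array([len(i) for i in islands]) if islands else np.array([0])
    return {
        "count": len(islands),
        "mean": float(sizes.mean()) if len(islands) else 0.0,
        "sd": float(sizes.std(ddof=1)) if len(islands) > 1 else 0.0,
        "median": float(np.median(sizes)) if len(islands) else 0.0,
    }


# ---------------------------------------------------------------------------
# resampling null

def resample_island_null(n_genes: int, clones, overlap: nx.Graph,
                         n_draws: int = 10_000, seed: int = 0,
                         observed_in_island: int | None = None
                         ) -> ResamplingNull:
    """Null distribution of the in-island gene fraction.

    Per draw, ``n_genes`` distinct clones are sampled uniformly without
    replacement and one gene placed on each; a sampled gene is in an
    island iff its clone overlaps another sampled clone. With
    ``observed_in_island`` given, a 1-df chi-squared test compares the
    observed (in-island, isolated) counts with the null-mean expectation.
    """
    clone_ids = sorted(c.id if hasattr(c, "id") else c for c in clones)
    n_clones = len(clone_ids)
    if n_genes > n_clones:
        raise ValueError("cannot place more genes than clones without "
                         "replacement")
    index = {c: i for i, c in enumerate(clone_ids)}
    rows, cols = [], []
    for a, b in overlap.edges:
        if a in index and b in index:
            rows += [index[a], index[b]]
            cols += [index[b], index[a]]
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_clones, n_clones))
    rng = np.random.default_rng([seed, 11])
    fractions = np.empty(n_draws)
    for d in range(n_draws):
        chosen = rng.choice(n_clones, size=n_genes, replace=False)
        mask = np.zeros(n_clones)
        mask[chosen] = 1.0
        neighbours = adj @ mask
        fractions[d] = float((neighbours[chosen] > 0).mean())
    mean = float(fractions.mean())
    sd = float(fractions.std(ddof=1))
    chi2 = np.nan
    p_value = np.nan
    if observed_in_island is not None:
        expected_in = mean * n_genes
        expected_out = (1.0 - mean) * n_genes
        observed_out = n_genes - observed_in_island
        if expected_in > 0 and expected_out > 0:
            chi2 = ((observed_in_island - expected_in) ** 2 / expected_in
                    + (observed_out - expected_out) ** 2 / expected_out)
            p_value = float(stats.chi2.sf(chi2, df=1))
    return ResamplingNull(n_draws=n_draws, fractions=fractions, mean=mean,
                          sd=sd, chi2=float(chi2), p_value=p_value,
                          seed=seed)
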