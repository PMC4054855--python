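"""Anchoring to deletion bins and genetic maps.

Terminal-deletion aneuploid lines each retain the proximal part of the arm
up to a breakpoint (a fraction of arm length); the intervals between
consecutive breakpoints are the deletion bins. A marker's presence/absence
pattern across the lines places it in a bin; contigs inherit the bins of
their markers (half-weighted across two consecutive bins). Bin physical
sizes come from the cumulative anchored contig length corrected by the
anchored fraction of the chromosome; genetic spans divided by those sizes
give the cM/Mb recombination profile. Recombination fractions convert to
map distances with the Kosambi function, and loci from other populations
project onto the framework map by interval-ratio interpolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeletionBin:
    name: str
    lo: float  # fraction of arm length, inclusive
    hi: float  # exclusive


def make_bins(breakpoints, prefix: str = "bin") -> list:
    """Nine bins from eight breakpoints: [0,b1), [b1,b2), ..., [b8,1]."""
    edges = [0.0, *breakpoints, 1.0]
    if any(b2 <= b1 for b1, b2 in zip(edges, edges[1:])):
        raise ValueError("breakpoints must be strictly increasing in (0,1)")
    return [
        DeletionBin(name=f"{prefix}{i + 1}-{lo:.2f}-{hi:.2f}", lo=lo, hi=hi)
        for i, (lo, hi) in enumerate(zip(edges, edges[1:]))
    ]


@dataclass
class BinAssignment:
    bins: list  # DeletionBin, centromere -> telomere
    markers: dict = field(default_factory=dict)  # bin name -> [marker ids]
    #: bin name -> {contig id: weight in {0.5, 1.0}}
    contig_weights: dict = field(default_factory=dict)
    #: bin name -> cumulative contig kb (weighted)
    cumulative_kb: dict = field(default_factory=dict)
    conflicts: list = field(default_factory=list)  # contigs left unassigned

    def total_kb(self) -> float:
        return sum(self.cumulative_kb.values())


@dataclass
class GeneticMapData:
    loci: list
    positions: list  # cM, nondecreasing in locus order
    population: str = ""

    def __post_init__(self):
        if any(b < a - 1e-9 for a, b in zip(self.positions,
                                            self.positions[1:])):
            raise ValueError("cM positions must be nondecreasing")

    def as_dict(self):
        return dict(zip(self.loci, self.positions))


@dataclass
class BinSizeEstimate:
    bin_name: str
    raw_kb: float
    corrected_mb: float
    cytogenetic_mb: float | None = None


# ---------------------------------------------------------------------------
# bin assignment

def assign_bin_from_deletion_pattern(presence, breakpoints, bins=None):
    """Bin of a marker from its presence flags across the deletion lines.

    ``presence`` is ordered by increasing breakpoint. A line with
    breakpoint b retains [0, b*length), so the expected pattern is a run
    of absences followed by presences; the marker falls between the
    largest absent breakpoint and the smallest present one. Non-monotone
    patterns return None (ambiguous).
    """
    breakpoints = list(breakpoints)
    if len(presence) != len(breakpoints):
        raise ValueError("one presence flag per deletion line required")
    bins = bins or make_bins(breakpoints)
    flags = [bool(f) for f in presence]
    # monotone check: once present, stays present
    seen_present = False
    for f in flags:
        if f:
            seen_present = True
        elif seen_present:
            return None
    n_absent = sum(1 for f in flags if not f)
    return bins[n_absent]


def assign_contigs_to_bins(marker_bins: dict, marker_contigs: dict,
                           contig_sizes: dict, bins) -> BinAssignment:
    """Place contigs into bins from their markers' bins.

    Markers all in one bin give the contig weight 1 there; markers in two
    consecutive bins give 0.5 each (the contig straddles the junction);
    markers in non-consecutive bins flag a conflict and the contig stays
    unassigned.
    """
    order = {b.name: i for i, b in enumerate(bins)}
    assignment = BinAssignment(bins=list(bins))
    for b in bins:
        assignment.markers[b.name] = []
        assignment.contig_weights[b.name] = {}
        assignment.cumulative_kb[b.name] = 0.0
    by_contig: dict = {}
    for marker, bin_name in marker_bins.items():
        if bin_name is None:
            continue
        assignment.markers[bin_name].append(marker)
        contig = marker_contigs.get(marker)
        if contig is not None:
            by_contig.setdefault(contig, set()).add(bin_name)
    for contig, bin_names in sorted(by_contig.items()):
        ranks = sorted(order[b] for b in bin_names)
        size = contig_sizes.get(contig, 0.0)
        if len(ranks) == 1:
            name = bins[ranks[0]].name
            assignment.contig_weights[name][contig] = 1.0
            assignment.cumulative_kb[name] += size
        elif len(ranks) == 2 and ranks[1] - ranks[0] == 1:
            for r in ranks:
                name = bins[r].name
                assignment.contig_weights[name][contig] = 0.5
                assignment.cumulative_kb[name] += 0.5 * size
        else:
            logger.warning("contig %s has markers in non-consecutive bins "
                           "%s; left unassigned", contig, sorted(bin_names))
            assignment.conflicts.append(contig)
    return assignment


# ---------------------------------------------------------------------------
# bin sizes and recombination ratios

def estimate_bin_sizes(assignment: BinAssignment, anchored_fraction: float,
                       cytogenetic_mb: dict | None = None) -> list:
    """Corrected bin sizes: cumulative anchored contig Mb divided by the
    anchored fraction of the chromosome."""
    if not (0.0 < anchored_fraction <= 1.0):
        raise ValueError("anchored_fraction must be in (0, 1]")
    cytogenetic_mb = cytogenetic_mb or {}
    out = []
    for b in assignment.bins:
        raw_kb = assignment.cumulative_kb.get(b.name, 0.0)
        out.append(BinSizeEstimate(
            bin_name=b.name,
            raw_kb=raw_kb,
            corrected_mb=raw_kb / 1000.0 / anchored_fraction,
            cytogenetic_mb=cytogenetic_mb.get(b.name),
        ))
    return out


def bin_size_range(estimates, skip_first: bool = True):
    """(min, max) corrected Mb over bins, excluding the centromeric row."""
    vals = [e.corrected_mb for e in (estimates[1:] if skip_first
                                     else estimates)]
    return min(vals), max(vals)


def compute_cm_mb(bin_spans_cm: dict, bin_sizes_mb: dict,
                  merge_rule=()) -> dict:
    """cM/Mb per (optionally merged) bin plus the whole-arm ratio.

    ``merge_rule`` lists tuples of bin names to combine before division
    (used where the genetic map cannot separate adjacent bins). Zero-Mb
    bins yield NaN and a warning.
    """
    merged_into = {}
    for group in merge_rule:
        label = "+".join(group)
        for name in group:
            merged_into[name] = label
    spans: dict = {}
    sizes: dict = {}
    for name, cm in bin_spans_cm.items():
        label = merged_into.get(name, name)
        spans[label] = spans.get(label, 0.0) + cm
        sizes[label] = sizes.get(label, 0.0) + bin_sizes_mb.get(name, 0.0)
    ratios = {}
    for label, cm in spans.items():
        mb = sizes[label]
        if mb == 0:
            logger.warning("bin %s has zero physical size; ratio undefined",
                           label)
            ratios[label] = math.nan
        else:
            ratios[label] = cm / mb
    total_cm = sum(bin_spans_cm.values())
    total_mb = sum(bin_sizes_mb.get(n, 0.0) for n in bin_spans_cm)
    ratios["whole_arm"] = total_cm / total_mb if total_mb else math.nan
    return ratios


def bin_genetic_spans(marker_bins: dict, marker_cm: dict) -> dict:
    """Genetic span of each bin: (max - min) cM over its mapped markers."""
    spans: dict = {}
    by_bin: dict = {}
    for marker, bin_name in marker_bins.items():
        if bin_name is not None and marker in marker_cm:
            by_bin.setdefault(bin_name, []).append(marker_cm[marker])
    for bin_name, positions in by_bin.items():
        spans[bin_name] = max(positions) - min(positions)
    return spans


# ---------------------------------------------------------------------------
# Kosambi and map projection

def kosambi_cm(r) -> float:
    """Kosambi map distance d = 25 * ln((1+2r)/(1-2r)) cM, r in [0, 0.5)."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r_arr) / (1 - 2 * r_arr))
    return float(d) if np.isscalar(r) else d


def project_neighbor_map(framework: GeneticMapData,
                         other: GeneticMapData) -> GeneticMapData:
    """Project the other map's loci onto the framework by interval ratios.

    Shared loci define intervals; a target locus at fraction f of the
    interval [A, B] on the other map lands at cA + f*(cB - cA) on the
    framework. Targets outside the shared range extrapolate from the
    nearest interval. Shared loci whose order disagrees between the maps
    are dropped (largest collinear subset kept) with a warning.
    """
    fw = framework.as_dict()
    ot = other.as_dict()
    shared = [loc for loc in other.loci if loc in fw]
    if len(shared) >= 2:
        shared = _largest_collinear(shared, fw, ot, other)
    if len(shared) < 2:
        raise ValueError("need >= 2 collinear shared loci to project")

    anchors = sorted(shared, key=lambda l: ot[l])
    a_pos = [ot[l] for l in anchors]
    a_cm = [fw[l] for l in anchors]
    merged = dict(fw)
    for loc in other.loci:
        if loc in fw:
            continue
        p = ot[loc]
        i = int(np.searchsorted(a_pos, p)) - 1
        i = min(max(i, 0), len(anchors) - 2)
        pa, pb = a_pos[i], a_pos[i + 1]
        ca, cb = a_cm[i], a_cm[i + 1]
        if pb == pa:
            merged[loc] = ca
        else:
            merged[loc] = ca + (cb - ca) * (p - pa) / (pb - pa)
    loci = sorted(merged, key=lambda l: (merged[l], l))
    return GeneticMapData(loci=loci, positions=[merged[l] for l in loci],
                          population=framework.population or "neighbor")


def _largest_collinear(shared, fw, ot, other):
    ordered = sorted(shared, key=lambda l: ot[l])
    values = [fw[l] for l in ordered]
    keep_idx = _longest_nondecreasing(values)
    dropped = set(range(len(ordered))) - set(keep_idx)
    if dropped:
        logger.warning("dropped non-collinear shared loci: %s",
                       [ordered[i] for i in sorted(dropped)])
    return [ordered[i] for i in keep_idx]


def _longest_nondecreasing(values):
    import bisect

    tails: list = []  # (value, index)
    parents = [-1] * len(values)
    idx_at: list = []
    for i, v in enumerate(values):
        j = bisect.bisect_right([t for t in tails], v)
        if j == len(tails):
            tails.append(v)
            idx_at.append(i)
        else:
            tails[j] = v
            idx_at[j] = i
        parents[i] = idx_at[j - 1] if j > 0 else -1
    out = []
    i = idx_at[-1] if idx_at else -1
    while i >= 0:
        out.append(i)
        i = parents[i]
    return list(reversed(out))


def marker_density(n_markers: int, span: float) -> float:
    """Markers per unit span (per Mb or per cM)."""
    if span <= 0:
        raise ValueError("span must be positive")
    return n_markers / span
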