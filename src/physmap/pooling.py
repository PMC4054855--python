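"""Pooled-library marker screening and deconvolution.

An arrayed clone set (384-well plates, 16 rows x 24 columns) is pooled
three-dimensionally: one pool per plate, one row pool and one column pool
spanning all plates, plus a super pool of everything. A marker screened
against the pools lights up the pools containing a clone that carries it;
deconvolution inverts the positive pool pattern back to individual clones,
using the physical-map contigs and fingerprint matches to resolve patterns
that a single clone cannot explain (the DSMP cases), or, for whole-library
plate pools, a segment scorer in the style of the Elephant anchoring tool.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import AssemblyParams, sulston_score

logger = logging.getLogger(__name__)

DECONV_CASES = ("SINGLE", "A_overlapping_pair", "B_cross_contig_pair",
                "C_pair_plus_matching_third", "D_two_matching_pairs",
                "UNIQUE_PAIR", "UNIQUE_TRIPLE", "SEGMENT", "UNRESOLVED")


@dataclass
class PoolingScheme:
    """3D pooling of an arrayed clone set.

    ``address[clone] = (plate, row, column)``; pools are identified as
    ``P<k>``, ``R<k>``, ``C<k>``. Row/column pools span all plates.
    """

    plate_rows: int
    plate_cols: int
    n_plates: int
    address: dict  # clone id -> (plate, row, col)
    clone_at: dict  # (plate, row, col) -> clone id

    @property
    def pool_ids(self):
        return ([f"P{p}" for p in range(self.n_plates)]
                + [f"R{r}" for r in range(self.plate_rows)]
                + [f"C{c}" for c in range(self.plate_cols)])

    def pools_of(self, clone_id):
        p, r, c = self.address[clone_id]
        return {f"P{p}", f"R{r}", f"C{c}"}

    def clones_in_pool(self, pool_id):
        kind, k = pool_id[0], int(pool_id[1:])
        dim = {"P": 0, "R": 1, "C": 2}[kind]
        return {cid for cid, addr in self.address.items() if addr[dim] == k}


@dataclass
class PoolScreenResult:
    marker_id: str
    positive_pools: set  # pool ids (3D scheme) or plate ids (plate pools)
    call_quality: dict = field(default_factory=dict)


@dataclass
class MarkerAssignment:
    marker_id: str
    clone_ids: list
    contig_ids: list
    evidence_case: str

    def __post_init__(self):
        if self.evidence_case not in DECONV_CASES:
            raise ValueError(f"unknown evidence case {self.evidence_case!r}")


@dataclass
class NormalizationRule:
    """Array-positivity thresholds: the mean + k*SD coefficient ladders per
    pool dimension, and the fraction/t-test rule used for multi-probe
    junction markers."""

    plate_ladder: tuple = (2.7, 2.6, 2.5, 2.4, 2.3, 2.2, 2.1, 2.0)
    row_ladder: tuple = (2.8, 2.7, 2.6, 2.5, 2.4, 2.3, 2.2, 2.1)
    column_ladder: tuple = (3.0, 2.9, 2.8, 2.7, 2.6, 2.5, 2.4, 2.3, 2.2)
    isbp_k: float = 2.0
    isbp_p_threshold: float = 0.05
    isbp_probe_fraction: float = 0.75

    def __post_init__(self):
        for ladder in (self.plate_ladder, self.row_ladder, self.column_ladder):
            if any(b >= a for a, b in zip(ladder, ladder[1:])):
                raise ValueError(
                    "coefficient ladders must be strictly decreasing")

    def ladder(self, dimension):
        return {"plate": self.plate_ladder, "row": self.row_ladder,
                "column": self.column_ladder}[dimension]


# ---------------------------------------------------------------------------
# pooling scheme

def build_pooling(clones, plate_rows: int = 16, plate_cols: int = 24,
                  n_plates: int | None = None) -> PoolingScheme:
    """Fill clones into plates plate-major, row-major, and derive the 3D
    pools. 8,597 clones in 16x24 plates need ceil(8597/384) = 23 plates."""
    clone_ids = [c if isinstance(c, str) else c.id for c in clones]
    per_plate = plate_rows * plate_cols
    needed = math.ceil(len(clone_ids) / per_plate)
    if n_plates is None:
        n_plates = needed
    elif len(clone_ids) > n_plates * per_plate:
        raise ValueError(
            f"{len(clone_ids)} clones overflow {n_plates} plates of "
            f"{per_plate} wells")
    address = {}
    clone_at = {}
    for k, cid in enumerate(clone_ids):
        plate, well = divmod(k, per_plate)
        row, col = divmod(well, plate_cols)
        address[cid] = (plate, row, col)
        clone_at[(plate, row, col)] = cid
    return PoolingScheme(plate_rows=plate_rows, plate_cols=plate_cols,
                         n_plates=n_plates, address=address,
                         clone_at=clone_at)


# ---------------------------------------------------------------------------
# simulated screens

def simulate_screen(scheme: PoolingScheme, marker, clones, error_model=None,
                    seed: int = 0) -> PoolScreenResult:
    """Screen one marker against the 3D pools.

    A pool is truly positive iff it contains a clone whose interval covers
    the marker position; false-negative/-positive rates then flip calls
    independently per pool. Deterministic given the seed.
    """
    error_model = error_model or {"false_neg": 0.0, "false_pos": 0.0}
    rng = np.random.default_rng([seed, zlib.crc32(marker.id.encode())])
    truly = set()
    for clone in clones:
        if clone.id in scheme.address and clone.covers(marker.pos):
            truly |= scheme.pools_of(clone.id)
    positives = set()
    for pool in scheme.pool_ids:
        if pool in truly:
            if rng.random() >= error_model["false_neg"]:
                positives.add(pool)
        else:
            if rng.random() < error_model["false_pos"]:
                positives.add(pool)
    return PoolScreenResult(marker_id=marker.id, positive_pools=positives)


def simulate_plate_screen(marker, clones, plate_map, n_plates,
                          error_model=None, seed: int = 0) -> PoolScreenResult:
    """Screen one marker against whole-library plate pools.

    ``plate_map`` maps clone id -> library plate index.
    """
    error_model = error_model or {"false_neg": 0.0, "false_pos": 0.0}
    rng = np.random.default_rng([seed, 1, zlib.crc32(marker.id.encode())])
    truly = {plate_map[c.id] for c in clones
             if c.id in plate_map and c.covers(marker.pos)}
    positives = set()
    for plate in range(n_plates):
        if plate in truly:
            if rng.random() >= error_model["false_neg"]:
                positives.add(plate)
        elif rng.random() < error_model["false_pos"]:
            positives.add(plate)
    return PoolScreenResult(marker_id=marker.id, positive_pools=positives)


# ---------------------------------------------------------------------------
# array-positivity normalisation

def call_positives_mean_sd(intensities: pd.DataFrame, pool_dims: dict,
                           rule: NormalizationRule | None = None
                           ) -> pd.DataFrame:
    """Mean + k*SD ladder calls.

    ``intensities``: pools x probes. ``pool_dims``: pool id -> dimension
    ('plate'/'row'/'column'). Per probe and dimension the coefficient
    ladder is walked from most to least stringent; the first k yielding at
    least one pool with signal > mean + k*SD (mean/SD across that
    dimension's pools) fixes the calls. SD = 0 probes are skipped.

    Returns a boolean pools x probes frame.
    """
    rule = rule or NormalizationRule()
    calls = pd.DataFrame(False, index=intensities.index,
                         columns=intensities.columns)
    for dim in ("plate", "row", "column"):
        pools = [p for p in intensities.index if pool_dims.get(p) == dim]
        if not pools:
            continue
        block = intensities.loc[pools]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        for probe in intensities.columns:
            if sd[probe] == 0 or not np.isfinite(sd[probe]):
                logger.info("probe %s: zero SD in %s pools, skipped",
                            probe, dim)
                continue
            for k in rule.ladder(dim):
                thr = mean[probe] + k * sd[probe]
                hit = block[probe] > thr
                if hit.any():
                    calls.loc[pools, probe] = hit
                    break
    return calls


def _remove_intensity_trend(values: np.ndarray, reference: np.ndarray
                            ) -> np.ndarray:
    """Lowess-style correction: subtract the smooth trend of ``values``
    against the reference intensity, leaving residuals with no
    intensity-dependent drift."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    order = np.argsort(reference)
    smoothed = lowess(values[order], reference[order], frac=0.5,
                      return_sorted=False)
    out = values.copy()
    out[order] = values[order] - smoothed
    return out


def call_positives_isbp(intensities: pd.DataFrame, probe_to_marker: dict,
                        rule: NormalizationRule | None = None,
                        empty_spots=None) -> pd.DataFrame:
    """Junction-marker (multi-probe) positivity calls.

    Per pool: background-subtract (median of the designated empty spots),
    log2, remove the smooth intensity-dependent trend, centre by the
    median and scale by the SD. A marker is positive in a pool iff at
    least ``isbp_probe_fraction`` of its probes exceed mean + isbp_k*SD of
    the pool's normalised signal and a one-sample t-test of its probes
    against the pool mean gives p < ``isbp_p_threshold``.

    Returns a boolean pools x markers frame.
    """
    rule = rule or NormalizationRule()
    markers = sorted(set(probe_to_marker.values()))
    by_marker = {m: [p for p, mm in probe_to_marker.items() if mm == m]
                 for m in markers}
    for m, probes in by_marker.items():
        if len(probes) < 2:
            raise ValueError(f"marker {m} has < 2 probes; t-test impossible")
    if empty_spots is None:
        logger.warning("no empty spots designated; background step skipped")
    probe_cols = [c for c in intensities.columns
                  if empty_spots is None or c not in empty_spots]

    calls = pd.DataFrame(False, index=intensities.index, columns=markers)
    for pool in intensities.index:
        # trend reference: the other pools' median per probe, so a pool's
        # own signal cannot be smoothed away as an intensity trend
        others = intensities.loc[intensities.index != pool, probe_cols]
        ref = others.median(axis=0).to_numpy(dtype=float)
        sig = intensities.loc[pool, probe_cols].to_numpy(dtype=float)
        if empty_spots is not None:
            bg = float(np.median(intensities.loc[pool, list(empty_spots)]))
            sig = sig - bg
        sig = np.log2(np.maximum(sig, 1e-9))
        sig = _remove_intensity_trend(sig, np.log2(np.maximum(ref, 1e-9)))
        sig = sig - np.median(sig)
        sd = sig.std(ddof=1)
        if sd > 0:
            sig = sig / sd
        normalized = pd.Series(sig, index=probe_cols)
        pool_mean = float(normalized.mean())
        pool_sd = float(normalized.std(ddof=1))
        thr = pool_mean + rule.isbp_k * pool_sd
        for m in markers:
            probes = normalized[by_marker[m]]
            frac = float((probes > thr).mean())
            if frac < rule.isbp_probe_fraction:
                continue
            t_res = stats.ttest_1samp(probes, pool_mean,
                                      alternative="greater")
            calls.loc[pool, m] = bool(t_res.pvalue < rule.isbp_p_threshold)
    return calls


# ---------------------------------------------------------------------------
# DSMP deconvolution (3D MTP pools)

_MATCH_CUTOFF = 1e-25
_MAX_CANDIDATES = 60  # combinatorial guard; beyond this the call is hopeless
_MAX_RUN = 4  # longest same-contig overlapping run considered


def _fp_match(a, b, fingerprints, params):
    return sulston_score(fingerprints[a], fingerprints[b],
                         params) <= _MATCH_CUTOFF


def dsmp_deconvolute(result: PoolScreenResult, scheme: PoolingScheme,
                     contigs, fingerprints,
                     params: AssemblyParams | None = None,
                     max_spurious: int = 2) -> MarkerAssignment:
    """Resolve a 3D pool screen to clones via the DSMP case ladder.

    Candidates are clones whose (plate, row, column) address lies in the
    positive pools. In order, the first explanation whose clones' pool
    addresses cover every positive pool wins: a single clone; a run of
    overlapping clones in one contig (case A; a pair in the simplest
    form); two clones from different contigs with a fingerprint match at
    1e-25 (case B); an overlapping pair plus a matching third clone from
    another contig (case C); two overlapping pairs in different contigs
    joined by a cross-pair match (case D).

    Screens are noisy, so if no exact explanation exists the ladder is
    retried tolerating up to ``max_spurious`` unexplained positive pools
    (likely false positives), with candidate clones then also allowed to
    miss one of their three pools (a likely false negative).
    """
    params = params or AssemblyParams()
    positives = set(result.positive_pools)
    if not positives:
        return MarkerAssignment(result.marker_id, [], [], "UNRESOLVED")

    contig_of = {}
    cb_span = {}
    rank_of = {}
    end_dist = {}
    for contig in contigs:
        n = len(contig.clones)
        for k, cid in enumerate(contig.clones):
            contig_of[cid] = contig.id
            rank_of[cid] = k
            end_dist[cid] = min(k, n - 1 - k)
            start = contig.cb.get(cid, 0.0)
            n_bands = len(fingerprints[cid]) if cid in fingerprints else 0
            cb_span[cid] = (start, start + n_bands)
    # unassembled clones act as singleton contigs so the cross-contig
    # cases can still link them through fingerprint matches
    for cid in scheme.address:
        if cid not in contig_of and cid in fingerprints:
            contig_of[cid] = f"singleton:{cid}"
            rank_of[cid] = 0
            cb_span[cid] = (0.0, float(len(fingerprints[cid])))

    attempts = [(0, False)] + [(k, True) for k in range(1, max_spurious + 1)]
    for fp_tol, relax in attempts:
        asg = _dsmp_attempt(result.marker_id, positives, scheme, contig_of,
                            cb_span, rank_of, end_dist, fingerprints,
                            params, fp_tol, relax)
        if asg == "AMBIGUOUS":
            # several exact explanations exist; escalating the noise
            # tolerance could only pick between them arbitrarily
            break
        if asg is not None:
            return asg
    return MarkerAssignment(result.marker_id, [], [], "UNRESOLVED")


def _dsmp_attempt(marker_id, positives, scheme, contig_of, cb_span, rank_of,
                  end_dist, fingerprints, params, fp_tol, relax):
    pos_p = {int(p[1:]) for p in positives if p.startswith("P")}
    pos_r = {int(p[1:]) for p in positives if p.startswith("R")}
    pos_c = {int(p[1:]) for p in positives if p.startswith("C")}
    full = []
    partial = []
    for cid, (p, r, c) in scheme.address.items():
        if cid not in fingerprints:
            continue
        n_hit = (p in pos_p) + (r in pos_r) + (c in pos_c)
        if n_hit == 3:
            full.append(cid)
        elif relax and n_hit == 2:
            partial.append(cid)
    if len(partial) > _MAX_CANDIDATES:
        partial = []
    candidates = sorted(full) + sorted(partial)
    if not candidates or len(candidates) > 2 * _MAX_CANDIDATES:
        return None

    def explains(clone_set):
        union = set()
        for c in clone_set:
            union |= scheme.pools_of(c)
        return len(positives - union) <= fp_tol

    def overlapping(a, b):
        """Same contig and CB intervals intersect, or near in the clone
        order (buried clones can distort CB placement)."""
        if contig_of.get(a) is None or contig_of.get(a) != contig_of.get(b):
            return False
        (a0, a1), (b0, b1) = cb_span[a], cb_span[b]
        if a0 < b1 and b0 < a1:
            return True
        return abs(rank_of[a] - rank_of[b]) <= 3

    def assignment(clone_set, case):
        ctgs = sorted({contig_of[c] for c in clone_set if c in contig_of})
        return MarkerAssignment(marker_id, sorted(clone_set), ctgs, case)

    # single clone (must be unique when tolerating noise)
    singles = [c for c in candidates if explains({c})]
    if len(singles) == 1 or (fp_tol == 0 and singles):
        return assignment({singles[0]}, "SINGLE")

    # case A: a run of overlapping clones within one contig
    by_contig: dict = {}
    for c in candidates:
        ctg = contig_of.get(c)
        if ctg is not None:
            by_contig.setdefault(ctg, []).append(c)
    for ctg in sorted(by_contig):
        members = sorted(by_contig[ctg], key=lambda c: (cb_span[c], c))
        for size in range(2, min(_MAX_RUN, len(members)) + 1):
            for i in range(len(members) - size + 1):
                run = members[i:i + size]
                if not all(overlapping(a, b)
                           for a, b in zip(run, run[1:])):
                    continue
                if explains(set(run)):
                    return assignment(set(run), "A_overlapping_pair")

    pairs = [(a, b) for i, a in enumerate(candidates)
             for b in candidates[i + 1:]]
    # case B: cross-contig pair with a fingerprint match
    for a, b in pairs:
        if (contig_of.get(a) != contig_of.get(b)
                and explains({a, b})
                and _fp_match(a, b, fingerprints, params)):
            return assignment({a, b}, "B_cross_contig_pair")
    # case C: overlapping pair + matching third clone from another contig
    adj_pairs = [(a, b) for a, b in pairs if overlapping(a, b)]
    for a, b in adj_pairs:
        for c in candidates:
            if c in (a, b) or contig_of.get(c) == contig_of.get(a):
                continue
            if not explains({a, b, c}):
                continue
            if (_fp_match(a, c, fingerprints, params)
                    or _fp_match(b, c, fingerprints, params)):
                return assignment({a, b, c}, "C_pair_plus_matching_third")
    # case D: two overlapping pairs in different contigs, cross-pair match
    for i, (a, b) in enumerate(adj_pairs):
        for c, d in adj_pairs[i + 1:]:
            if contig_of.get(a) == contig_of.get(c):
                continue
            if not explains({a, b, c, d}):
                continue
            if any(_fp_match(x, y, fingerprints, params)
                   for x in (a, b) for y in (c, d)):
                return assignment({a, b, c, d}, "D_two_matching_pairs")
    # fallback: a single candidate pair explaining the pattern exactly is
    # accepted even without contig or fingerprint support (e.g. a marker
    # at the junction between two abutting contigs); uniqueness keeps
    # this safe
    if fp_tol == 0 and not relax:
        exact = [(a, b) for a, b in pairs if explains({a, b})]
        if len(exact) == 1:
            return assignment(set(exact[0]), "UNIQUE_PAIR")
        if len(exact) > 1:
            # the classic 2x2 row/column ambiguity: several pairs explain
            # the pattern; keep the one whose members' fingerprints show a
            # significant mutual overlap, if that singles one out
            strong = [
                (a, b) for a, b in exact
                if sulston_score(fingerprints[a], fingerprints[b],
                                 params) <= params.net_cutoff]
            if len(strong) == 1:
                return assignment(set(strong[0]), "UNIQUE_PAIR")
            return "AMBIGUOUS"
        # exact triples built on an overlapping same-contig pair (markers
        # at a junction covered by three clones across two contigs)
        triples = []
        for a, b in adj_pairs:
            for c in candidates:
                if c in (a, b) or not explains({a, b, c}):
                    continue
                if {a, b, c} not in [set(t) for t in triples]:
                    triples.append((a, b, c))
        if len(triples) > 1:
            # contigs abut only at their termini, so a genuine junction
            # triple has all members near a contig end
            near_end = [t for t in triples
                        if all(end_dist.get(c, 0) <= 3 for c in t)]
            if near_end:
                triples = near_end
        if len(triples) == 1:
            return assignment(set(triples[0]), "UNIQUE_TRIPLE")
        if len(triples) > 1:
            # prefer the triple whose third clone shows fingerprint
            # affinity with the pair, but only with a decisive margin
            def support(triple):
                a, b, c = triple
                return min(
                    sulston_score(fingerprints[c], fingerprints[x], params)
                    for x in (a, b))

            scored = sorted((support(t), t) for t in triples)
            if scored[0][0] <= 1e-3 * scored[1][0] and scored[0][0] <= 1e-3:
                return assignment(set(scored[0][1]), "UNIQUE_TRIPLE")
            return "AMBIGUOUS"
    return None


# ---------------------------------------------------------------------------
# Elephant-style segment deconvolution (whole-library plate pools)

def contig_segments(contigs, branch_nodes=None):
    """Split contigs into segments at branching clones (skeleton degree
    > 2). Validated linear contigs are single segments."""
    segments = []
    branch_nodes = branch_nodes or set()
    for contig in contigs:
        seg: list = []
        for cid in contig.clones:
            if cid in branch_nodes:
                if seg:
                    segments.append((contig.id, seg))
                segments.append((contig.id, [cid]))
                seg = []
            else:
                seg.append(cid)
        if seg:
            segments.append((contig.id, seg))
    return segments


def segment_deconvolute(result: PoolScreenResult, contigs, plate_map,
                        threshold: float = 13.0,
                        weights: tuple = (5.0, -2.0, -1.0),
                        branch_nodes=None) -> MarkerAssignment:
    """Assign a plate-pool screen to a unique contig segment.

    Segment score = w_hit * (positive plates holding >= 1 segment clone)
    + w_miss * (positive plates holding none) + w_stray * (segment clones
    sitting in negative plates), with weights (5, -2, -1). The marker is
    assigned iff exactly one segment scores >= threshold.
    """
    positives = set(result.positive_pools)
    if not positives:
        return MarkerAssignment(result.marker_id, [], [], "UNRESOLVED")
    w_hit, w_miss, w_stray = weights
    winners = []
    for contig_id, seg in contig_segments(contigs, branch_nodes):
        seg_plates = {plate_map[c] for c in seg if c in plate_map}
        hit = len(positives & seg_plates)
        miss = len(positives - seg_plates)
        stray = sum(1 for c in seg
                    if c in plate_map and plate_map[c] not in positives)
        score = w_hit * hit + w_miss * miss + w_stray * stray
        if score >= threshold:
            winners.append((contig_id, seg, score))
    if len(winners) != 1:
        return MarkerAssignment(result.marker_id, [], [], "UNRESOLVED")
    contig_id, seg, _score = winners[0]
    seg_clones = sorted(c for c in seg
                        if c in plate_map and plate_map[c] in positives)
    return MarkerAssignment(result.marker_id, seg_clones or sorted(seg),
                            [contig_id], "SEGMENT")
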