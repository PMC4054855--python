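"""Fingerprint-overlap contig assembly.

Clone overlap is measured by the Sulston score: the probability that two
fingerprints share their observed number of bands by chance, with each
band-pair matching independently with probability p = 2*tolerance*nH/G
(nH the larger band count, G the gel length in the same mobility units).
Low scores indicate true overlap.

The assembly follows the linear-topology procedure: a permissive net of
significant overlaps, subnets at a stricter cut-off that become contig
candidates, validation of candidates by size and by the linearity of a
transitive-reduction skeleton (net width), elimination of questionable (Q)
clones from non-linear candidates, and a final re-split of recalcitrant
components at an even stricter cut-off. Validated linear contigs receive
consensus-band (CB) coordinates from which a minimal tiling path and
assembly statistics are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

try:  # pairwise band matching is the hot loop; compile it when possible
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco


@dataclass
class Fingerprint:
    """A clone's multiset of restriction-band sizes (mobility units), sorted."""

    clone_id: str
    bands: np.ndarray

    def __post_init__(self):
        self.bands = np.sort(np.asarray(self.bands, dtype=float))

    def __len__(self):
        return len(self.bands)


@dataclass
class AssemblyParams:
    """Assembly cut-offs and units.

    The default preset is the linear-topology procedure (tolerance 12,
    gel length 60,000, net/subnet/strict cut-offs 1e-15/1e-25/1e-30,
    contigs of 5-999 clones). ``fpc_preset`` gives the classic
    high-stringency incremental-build parameters as an alternative.
    """

    tolerance: float = 12.0
    gel_length: float = 60_000.0
    net_cutoff: float = 1e-15
    subnet_cutoff: float = 1e-25
    strict_cutoff: float = 1e-30
    min_contig: int = 5
    max_contig: int = 999
    q_fraction: float = 0.10
    from_end: int = 0  # inert preset field (FPC semantics undefined here)

    def __post_init__(self):
        if not (self.net_cutoff >= self.subnet_cutoff >= self.strict_cutoff):
            raise ValueError("cut-offs must satisfy net >= subnet >= strict")
        if self.min_contig < 2:
            raise ValueError("min_contig must be >= 2")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")

    @classmethod
    def fpc_preset(cls) -> "AssemblyParams":
        """Classic FPC-style preset: incremental build at 1e-75 with
        single-to-end merging up to 1e-45, DQer at 10%, gel length 56,000."""
        return cls(tolerance=12.0, gel_length=56_000.0, net_cutoff=1e-45,
                   subnet_cutoff=1e-75, strict_cutoff=1e-75, from_end=55)


@dataclass
class MTPParams:
    min_overlap: float = 30.0  # CB units
    max_overlap: float = 250.0  # CB units
    from_end: float = 0.0
    min_shared_bands: int = 12

    def __post_init__(self):
        if not (0 < self.min_overlap < self.max_overlap):
            raise ValueError("need 0 < min_overlap < max_overlap")


@dataclass
class Contig:
    id: str
    clones: list  # ordered clone ids (CB order when validated)
    cb: dict  # clone id -> consensus-band coordinate
    width: int
    validated: bool
    cb_span: float = 0.0
    size_kb: float | None = None

    def __len__(self):
        return len(self.clones)


@dataclass
class AssemblyStats:
    n_contigs: int
    total_kb: float
    coverage_fraction: float
    n50_kb: float
    l50: int


@dataclass
class AssemblyResult:
    contigs: list
    unassembled: list  # clone ids in no validated/reported contig

    def all_clones(self):
        out = set(self.unassembled)
        for c in self.contigs:
            out.update(c.clones)
        return out


# ---------------------------------------------------------------------------
# band matching and Sulston score

def match_bands(a: Fingerprint, b: Fingerprint, tolerance: float) -> int:
    """Maximum one-to-one matching size between two sorted band lists,
    bands matching when their sizes differ by at most ``tolerance``.

    Two-pointer greedy on the sorted lists; for points on a line this
    attains the maximum matching.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return int(_match_sorted(np.asarray(a.bands, dtype=float),
                             np.asarray(b.bands, dtype=float),
                             float(tolerance)))


@njit(cache=True)
def _match_sorted(a, b, tol):  # pragma: no cover - exercised via match_bands
    i = 0
    j = 0
    count = 0
    while i < a.shape[0] and j < b.shape[0]:
        d = a[i] - b[j]
        if d < -tol:
            i += 1
        elif d > tol:
            j += 1
        else:
            count += 1
            i += 1
            j += 1
    return count


@njit(cache=True)
def _pairwise_counts(bands, lengths, tol):  # pragma: no cover
    n = bands.shape[0]
    out = np.zeros((n, n), dtype=np.int32)
    for x in range(n):
        for y in range(x + 1, n):
            i = 0
            j = 0
            count = 0
            na = lengths[x]
            nb = lengths[y]
            while i < na and j < nb:
                d = bands[x, i] - bands[y, j]
                if d < -tol:
                    i += 1
                elif d > tol:
                    j += 1
                else:
                    count += 1
                    i += 1
                    j += 1
            out[x, y] = count
            out[y, x] = count
    return out


def _all_pair_counts(fingerprints, tolerance):
    n = len(fingerprints)
    max_len = max((len(fp) for fp in fingerprints), default=0)
    bands = np.full((n, max(max_len, 1)), 1e12)
    lengths = np.zeros(n, dtype=np.int64)
    for i, fp in enumerate(fingerprints):
        bands[i, :len(fp)] = fp.bands
        lengths[i] = len(fp)
    return _pairwise_counts(bands, lengths, float(tolerance))


def _log10_binom_sf(m, n, p):
    """log10 of sum_{k=m..n} C(n,k) p^k (1-p)^(n-k), stable for tiny tails."""
    if m <= 0:
        return 0.0
    if m > n:
        return -math.inf
    k = np.arange(m, n + 1)
    logp = math.log(p) if p > 0 else -math.inf
    log1mp = math.log1p(-p) if p < 1 else -math.inf
    logterms = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
                + k * logp + (n - k) * log1mp)
    return float(logsumexp(logterms) / math.log(10))


def sulston_score(a: Fingerprint, b: Fingerprint,
                  params: AssemblyParams | None = None) -> float:
    """Probability that the two fingerprints share their observed number of
    bands by chance (binomial upper tail). Symmetric; lower = stronger."""
    params = params or AssemblyParams()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("fingerprints must have at least one band")
    n_lo, n_hi = sorted((len(a), len(b)))
    m = match_bands(a, b, params.tolerance)
    p = min(1.0, 2.0 * params.tolerance * n_hi / params.gel_length)
    return float(binom.sf(m - 1, n_lo, p))


def sulston_log10(a: Fingerprint, b: Fingerprint,
                  params: AssemblyParams | None = None) -> float:
    """log10 Sulston score, exact even where the probability underflows."""
    params = params or AssemblyParams()
    n_lo, n_hi = sorted((len(a), len(b)))
    m = match_bands(a, b, params.tolerance)
    p = min(1.0, 2.0 * params.tolerance * n_hi / params.gel_length)
    return _log10_binom_sf(m, n_lo, p)


# ---------------------------------------------------------------------------
# overlap nets

def _pairwise_scores(fingerprints, params):
    """Shared-band counts and log10 Sulston scores for all clone pairs."""
    counts = _all_pair_counts(fingerprints, params.tolerance)
    n = len(fingerprints)
    lens = np.array([len(fp) for fp in fingerprints])
    n_lo = np.minimum.outer(lens, lens)
    n_hi = np.maximum.outer(lens, lens)
    p = np.minimum(1.0, 2.0 * params.tolerance * n_hi / params.gel_length)
    with np.errstate(divide="ignore"):
        log10s = np.log10(binom.sf(counts - 1, n_lo, p))
    # recompute exactly where the double-precision tail underflowed
    for x, y in zip(*np.where(~np.isfinite(log10s))):
        if x < y:
            val = _log10_binom_sf(int(counts[x, y]), int(n_lo[x, y]),
                                  float(p[x, y]))
            log10s[x, y] = val
            log10s[y, x] = val
    return counts, log10s


def build_net(fingerprints, params: AssemblyParams | None = None,
              cutoff: float | None = None) -> nx.Graph:
    """Undirected overlap net: edge (a, b) iff Sulston score <= cutoff.

    Edges carry ``log10_score`` and ``shared`` (matched band count).
    """
    params = params or AssemblyParams()
    if len(fingerprints) < 2:
        raise ValueError("need at least two fingerprints")
    cutoff = params.net_cutoff if cutoff is None else cutoff
    counts, log10s = _pairwise_scores(fingerprints, params)
    return _graph_at_cutoff(fingerprints, counts, log10s, cutoff)


def _graph_at_cutoff(fingerprints, counts, log10s, cutoff):
    log_cut = math.log10(cutoff) if cutoff > 0 else -math.inf
    g = nx.Graph()
    ids = [fp.clone_id for fp in fingerprints]
    g.add_nodes_from(ids)
    n = len(ids)
    del n
    xs, ys = np.where(np.triu(log10s <= log_cut + 1e-12, k=1))
    for x, y in zip(xs, ys):
        g.add_edge(ids[x], ids[y], log10_score=float(log10s[x, y]),
                   shared=int(counts[x, y]))
    return g


# ---------------------------------------------------------------------------
# linearity / skeleton

def _edge_strength(g: nx.Graph) -> dict:
    """Total order on edge strength: primarily the log score (smaller =
    stronger), ties broken by more shared bands, then clone ids, so that
    equal-score edges never deadlock the reduction."""
    strength = {}
    for a, b, d in g.edges(data=True):
        lo, hi = (a, b) if a <= b else (b, a)
        key = (d["log10_score"], -d["shared"], lo, hi)
        strength[(a, b)] = key
        strength[(b, a)] = key
    return strength


def _skeleton(g: nx.Graph) -> nx.Graph:
    """Transitive-reduction skeleton: drop edge (a, c) when some common
    neighbour b overlaps both more strongly (smaller log-score, total
    order) and shares at least as many bands with each as a and c share
    with each other."""
    strength = _edge_strength(g)
    nbrs = {v: set(g[v]) for v in g}
    shared = {}
    for a, b, d in g.edges(data=True):
        shared[(a, b)] = d["shared"]
        shared[(b, a)] = d["shared"]
    skel = nx.Graph()
    skel.add_nodes_from(g.nodes)
    for a, c, data in g.edges(data=True):
        s_ac = strength[(a, c)]
        sh_ac = data["shared"]
        dominated = False
        for b in nbrs[a] & nbrs[c]:
            if (strength[(a, b)] < s_ac and strength[(b, c)] < s_ac
                    and shared[(a, b)] >= sh_ac and shared[(b, c)] >= sh_ac):
                dominated = True
                break
        if not dominated:
            skel.add_edge(a, c, **data)
    return skel


def _width_of_skeleton(skel: nx.Graph) -> int:
    branch = sum(1 for _, d in skel.degree() if d > 2)
    cycles = (skel.number_of_edges() - skel.number_of_nodes()
              + nx.number_connected_components(skel))
    return branch + cycles


def check_linearity(component: nx.Graph,
                    params: AssemblyParams | None = None) -> int:
    """Net width of a connected component.

    0 means the overlap skeleton is a simple path. If the raw width exceeds
    1 but removing a single clone brings it to 0 (one clone explains the
    non-linearity), the reported width is 1.
    """
    if component.number_of_nodes() > 1 and not nx.is_connected(component):
        raise ValueError("check_linearity expects a connected component")
    w0 = _width_of_skeleton(_skeleton(component))
    if w0 <= 1:
        return w0
    q, w_removed = _best_single_removal(component)
    if q is not None and w_removed == 0:
        return 1
    return w0


_MAX_REMOVAL_CANDIDATES = 25


def _best_single_removal(g: nx.Graph, candidates=None):
    """Clone whose removal minimises total skeleton width over the remaining
    components; ties broken by smaller resulting width then clone id."""
    best = (None, _total_width(g))
    if candidates is None:
        candidates = _defect_candidates(g)
    for node in sorted(candidates)[:_MAX_REMOVAL_CANDIDATES]:
        saved = list(g.edges(node, data=True))
        g.remove_node(node)
        w = _total_width(g)
        g.add_node(node)
        g.add_edges_from(saved)
        if w < best[1]:
            best = (node, w)
    return best


def _total_width(g: nx.Graph) -> int:
    total = 0
    for comp in nx.connected_components(g):
        total += _width_of_skeleton(_skeleton(g.subgraph(comp)))
    return total


def _defect_candidates(g: nx.Graph, skel: nx.Graph | None = None):
    """Nodes plausibly responsible for non-linearity: skeleton branch nodes,
    their neighbours, and nodes on skeleton cycles."""
    if skel is None:
        skel = _skeleton(g)
    cand = set()
    for node, deg in skel.degree():
        if deg > 2:
            cand.add(node)
            cand.update(skel[node])
    for cycle in nx.cycle_basis(skel):
        cand.update(cycle)
    if not cand:
        cand = set(g.nodes)
    return cand


# ---------------------------------------------------------------------------
# consensus band map

def _order_path(skel: nx.Graph):
    """Clone order along a path skeleton, lexicographically smaller endpoint
    first. Raises if the skeleton is not a simple path."""
    nodes = list(skel.nodes)
    if len(nodes) == 1:
        return nodes
    ends = [v for v, d in skel.degree() if d == 1]
    if len(ends) != 2 or any(d > 2 for _, d in skel.degree()) \
            or not nx.is_connected(skel):
        raise ValueError("contig skeleton is not a simple path")
    start = min(ends)
    order = [start]
    prev = None
    cur = start
    while len(order) < len(nodes):
        nxt = [v for v in skel[cur] if v != prev]
        if len(nxt) != 1:
            raise ValueError("contig skeleton is not a simple path")
        prev, cur = cur, nxt[0]
        order.append(cur)
    return order


def _bury_pendants(g: nx.Graph):
    """Repeatedly detach skeleton leaves hanging off branch nodes.

    Such leaves are redundant (typically nested) clones: their only strong
    skeletal tie is to a clone that already continues the path in both
    directions. They are buried into their host clone rather than lost.
    Returns (skeleton of the thinned graph, {buried clone: host clone}).
    """
    buried = {}
    while True:
        skel = _skeleton(g)
        pend = []
        for v, deg in skel.degree():
            if deg == 1:
                host = next(iter(skel[v]))
                if skel.degree(host) > 2:
                    pend.append((v, host))
        if not pend:
            return skel, buried
        for v, host in pend:
            buried[v] = host
            g.remove_node(v)


def _resolve_buried(order, buried):
    """Insert buried clones directly after their (possibly also buried)
    host in the path order."""
    children: dict = {}
    for v, host in buried.items():
        while host in buried:
            host = buried[host]
        children.setdefault(host, []).append(v)
    out = []
    for clone in order:
        out.append(clone)
        out.extend(sorted(children.get(clone, ())))
    return out


def _linear_order(g: nx.Graph):
    """Path order of a component whose skeleton is linear after burying
    redundant pendant clones. Returns (order incl. buried clones,
    {buried: host}) or raises ValueError if no path exists."""
    if g.number_of_nodes() == 1:
        return list(g.nodes), {}
    h = g.copy()
    skel, buried = _bury_pendants(h)
    order = _order_path(skel)  # raises when not a simple path
    return _resolve_buried(order, buried), buried


def consensus_band_map(contig_clones, fingerprints,
                       params: AssemblyParams | None = None):
    """CB coordinates for a validated linear contig.

    Returns (ordered clone ids, {clone id: CB coordinate}). The first clone
    of the path (lexicographically smaller endpoint) sits at 0; each next
    clone advances by the number of its bands not matched to the previous
    clone's bands; clones buried into a host clone share its coordinate.
    """
    params = params or AssemblyParams()
    fps = {fp.clone_id: fp for fp in fingerprints}
    subset = [fps[c] for c in contig_clones]
    if len(subset) == 1:
        return [subset[0].clone_id], {subset[0].clone_id: 0.0}
    g = build_net(subset, params, cutoff=params.subnet_cutoff)
    if not nx.is_connected(g):
        raise ValueError("contig clones are not connected at the subnet cut-off")
    order, buried = _linear_order(g)
    return order, _cb_from_order(order, fps, params, buried)


def _cb_from_order(order, fps, params, buried=None):
    buried = buried or {}

    def resolve(c):
        while c in buried:
            c = buried[c]
        return c

    cb = {}
    prev = None
    for cur in order:
        if prev is None:
            cb[cur] = 0.0
        elif cur in buried and resolve(cur) in cb:
            cb[cur] = cb[resolve(cur)]
        else:
            anchor = resolve(prev)
            if anchor not in cb:
                anchor = prev
            m = match_bands(fps[anchor], fps[cur], params.tolerance)
            cb[cur] = cb[anchor] + (len(fps[cur]) - m)
        prev = cur
    return cb


# ---------------------------------------------------------------------------
# contig assembly pipeline

def assemble_contigs(fingerprints, params: AssemblyParams | None = None
                     ) -> AssemblyResult:
    """Assemble clones into validated linear contigs.

    Pipeline: connected components at the subnet cut-off; validation by
    size (min_contig..max_contig) and skeleton linearity (width <= 1, a
    single-clone non-linearity being eliminated as a Q clone); iterative Q
    clone elimination for failing components; a re-split of still-failing
    components at the strict cut-off; components below min_contig are
    reported as unassembled. Every input clone appears in exactly one
    contig or in the unassembled set.
    """
    params = params or AssemblyParams()
    fps = {fp.clone_id: fp for fp in fingerprints}
    if len(fingerprints) < 2:
        return AssemblyResult(contigs=[], unassembled=sorted(fps))
    counts, log10s = _pairwise_scores(fingerprints, params)
    subnet = _graph_at_cutoff(fingerprints, counts, log10s,
                              params.subnet_cutoff)
    strict = _graph_at_cutoff(fingerprints, counts, log10s,
                              params.strict_cutoff)

    raw_contigs: list = []
    unassembled: list = []
    # worklist of (component graph, q_done, strict_done); Q elimination is
    # attempted on fresh subnet components and once more after the strict
    # re-split, per the procedure's "eliminate Q clones for the
    # non-validated contigs" at both stages
    work = [(subnet.subgraph(comp).copy(), False, False)
            for comp in nx.connected_components(subnet)]
    while work:
        g, q_done, strict_done = work.pop()
        n = g.number_of_nodes()
        if n < params.min_contig:
            unassembled.extend(g.nodes)
            continue
        try:
            order, buried = _linear_order(g)
        except ValueError:
            order = None
        if order is not None:
            for chunk in _split_oversized(order, params):
                if len(chunk) < params.min_contig:
                    unassembled.extend(chunk)
                else:
                    cb = _cb_from_order(chunk, fps, params, buried)
                    raw_contigs.append((chunk, cb, 0, True))
            continue
        # single clone explaining the non-linearity -> eliminate it as Q
        q, w = _best_single_removal(g)
        if q is not None and w == 0:
            unassembled.append(q)
            g.remove_node(q)
            work.extend((g.subgraph(comp).copy(), q_done, strict_done)
                        for comp in nx.connected_components(g))
            continue
        if not q_done:
            removed = _eliminate_q_clones(g, params)
            if removed:
                unassembled.extend(removed)
                work.extend((g.subgraph(comp).copy(), True, strict_done)
                            for comp in nx.connected_components(g))
                continue
        if not strict_done:
            gs = strict.subgraph(g.nodes).copy()
            if gs.number_of_edges() < g.number_of_edges():
                work.extend((gs.subgraph(comp).copy(), False, True)
                            for comp in nx.connected_components(gs))
                continue
        # could not be linearised: report as an unvalidated contig
        clones = sorted(g.nodes)
        raw_contigs.append((clones, {c: 0.0 for c in clones},
                            _total_width(g), False))

    raw_contigs.sort(key=lambda item: min(item[0]))
    contigs = []
    for k, (clones, cb, width, validated) in enumerate(raw_contigs, start=1):
        span = (max(cb[c] + len(fps[c]) for c in clones) - min(cb.values())
                if cb else 0.0)
        contigs.append(Contig(id=f"ctg{k:05d}", clones=list(clones), cb=cb,
                              width=width, validated=validated, cb_span=span))
    return AssemblyResult(contigs=contigs, unassembled=sorted(unassembled))


def _split_oversized(order, params):
    """Break a linear clone order exceeding max_contig into nearly equal
    consecutive chunks, each within the validated size range."""
    n = len(order)
    if n <= params.max_contig:
        return [order]
    n_chunks = math.ceil(n / params.max_contig)
    bounds = np.linspace(0, n, n_chunks + 1).round().astype(int)
    return [order[a:b] for a, b in zip(bounds, bounds[1:])]


def _eliminate_q_clones(g, params):
    """Iteratively remove the clone whose deletion most reduces total
    skeleton width (the operational Q-clone definition). Stops when the
    width cannot be reduced further or a removal budget (q_fraction of
    the component) is exhausted."""
    removed = []
    budget = max(1, int(math.ceil(params.q_fraction * g.number_of_nodes())))
    current = _total_width(g)
    while len(removed) < budget and current > 0:
        q, w = _best_single_removal(g)
        if q is None or w >= current:
            break
        g.remove_node(q)
        removed.append(q)
        current = w
    return removed


# ---------------------------------------------------------------------------
# minimal tiling path

def select_mtp(contigs, fingerprints, params: MTPParams | None = None):
    """Greedy left-to-right minimal tiling path over each contig's CB map.

    From the current clone, the next MTP clone is the one giving the
    greatest CB extension whose CB overlap with the current clone lies in
    [min_overlap, max_overlap] and which shares at least min_shared_bands
    bands with it; when no clone qualifies, the largest-overlap extending
    clone is taken and a gap-risk warning recorded.

    Returns (mtp clone ids, warnings).
    """
    params = params or MTPParams()
    fps = {fp.clone_id: fp for fp in fingerprints}
    mtp: list = []
    warns: list = []
    tol_params = AssemblyParams()
    for contig in contigs:
        if len(contig.clones) == 1:
            mtp.append(contig.clones[0])
            continue
        cb = contig.cb
        ext = {c: cb[c] + len(fps[c]) for c in contig.clones}
        ordered = sorted(contig.clones, key=lambda c: (cb[c], c))
        cur = ordered[0]
        mtp.append(cur)
        contig_end = max(ext.values())
        while ext[cur] < contig_end:
            extenders = [c for c in ordered
                         if ext[c] > ext[cur] and c not in mtp]
            if not extenders:
                break
            qualified = []
            for c in extenders:
                overlap = ext[cur] - cb[c]
                shared = match_bands(fps[cur], fps[c], tol_params.tolerance)
                if (params.min_overlap <= overlap <= params.max_overlap
                        and shared >= params.min_shared_bands):
                    qualified.append(c)
            if qualified:
                nxt = max(qualified, key=lambda c: (ext[c], c))
            else:
                nxt = max(extenders, key=lambda c: (ext[cur] - cb[c], c))
                warns.append(
                    f"{contig.id}: no clone with overlap in "
                    f"[{params.min_overlap}, {params.max_overlap}] after "
                    f"{cur}; took {nxt} (gap risk)")
            mtp.append(nxt)
            cur = nxt
    return mtp, warns


# ---------------------------------------------------------------------------
# statistics

def assembly_stats(contigs, chromosome_length_kb: float,
                   kb_per_cb: float = 1.2) -> AssemblyStats:
    """N50/L50, totals and coverage from contig CB spans.

    ``kb_per_cb`` calibrates CB units to kb; the default corresponds to a
    mean insert size divided by a mean band count per clone (~129/107).
    Coverage may exceed 1 for redundant assemblies.
    """
    sizes = []
    for c in contigs:
        c.size_kb = c.cb_span * kb_per_cb if c.cb_span else len(c) * kb_per_cb
        sizes.append(c.size_kb)
    if not sizes:
        return AssemblyStats(0, 0.0, 0.0, 0.0, 0)
    sizes = sorted(sizes, reverse=True)
    total = float(sum(sizes))
    cum = 0.0
    l50 = 0
    n50 = 0.0
    for s in sizes:
        cum += s
        l50 += 1
        if cum >= total / 2.0:
            n50 = s
            break
    return AssemblyStats(
        n_contigs=len(sizes),
        total_kb=total,
        coverage_fraction=total / chromosome_length_kb,
        n50_kb=float(n50),
        l50=l50,
    )


def n50_l50(sizes):
    """(N50, L50) of a list of sizes, by the cumulative-sum definition."""
    stats = assembly_stats(
        [Contig(id=str(i), clones=[str(i)], cb={}, width=0, validated=True,
                cb_span=s) for i, s in enumerate(sizes)],
        chromosome_length_kb=1.0, kb_per_cb=1.0)
    return stats.n50_kb, stats.l50
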