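"""Fingerprint assembly: band matching, Sulston score, nets, contigs."""

import itertools

import networkx as nx
import numpy as np
import pytest

import physmap as pm
from physmap.assembly import (
    AssemblyParams,
    _skeleton,
    _width_of_skeleton,
    check_linearity,
    consensus_band_map,
    n50_l50,
)
from conftest import make_tiling_fingerprints


def fp(name, bands):
    return pm.Fingerprint(name, np.asarray(bands, dtype=float))


def brute_force_matching(a, b, tol):
    """Maximum one-to-one matching by exhaustive assignment search."""
    best = 0
    nb = len(b)
    for assign in itertools.product(range(nb + 1), repeat=len(a)):
        used = [x for x in assign if x < nb]
        if len(set(used)) != len(used):
            continue
        ok = all(x == nb or abs(a[i] - b[x]) <= tol
                 for i, x in enumerate(assign))
        if ok:
            best = max(best, len(used))
    return best


class TestMatchBands:
    @pytest.mark.parametrize("a, b, tol, expected", [
        ([100, 200, 300], [100, 200, 300], 12, 3),
        ([100, 200, 300], [111, 400], 12, 1),
        ([100, 105], [103], 12, 1),
        ([], [100], 12, 0),
        ([100], [200], 12, 0),
    ])
    def test_examples(self, a, b, tol, expected):
        assert pm.match_bands(fp("a", a), fp("b", b), tol) == expected

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            a = np.sort(rng.uniform(50, 500, rng.integers(1, 6)))
            b = np.sort(rng.uniform(50, 500, rng.integers(1, 6)))
            tol = float(rng.uniform(1, 60))
            got = pm.match_bands(fp("a", a), fp("b", b), tol)
            assert got == brute_force_matching(list(a), list(b), tol)

    def test_symmetric(self):
        a, b = fp("a", [60, 130, 260]), fp("b", [64, 250, 410])
        assert pm.match_bands(a, b, 12) == pm.match_bands(b, a, 12)


class TestSulston:
    def test_full_match_closed_form(self):
        a = fp("a", np.linspace(5_000, 45_000, 10))
        b = fp("b", np.linspace(5_000, 45_000, 10))
        # p = 2*12*10/60000 = 0.004; all 10 bands match -> p^10
        assert pm.sulston_score(a, b) == pytest.approx(1.048576e-24, rel=1e-9)

    def test_no_match_gives_one(self):
        a = fp("a", [5_000.0])
        b = fp("b", [45_000.0])
        assert pm.sulston_score(a, b) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = fp("a", rng.uniform(5_000, 50_000, 30))
        b = fp("b", rng.uniform(5_000, 50_000, 20))
        assert pm.sulston_score(a, b) == pm.sulston_score(b, a)

    def test_empty_fingerprint_rejected(self):
        with pytest.raises(ValueError):
            pm.sulston_score(fp("a", []), fp("b", [100]))

    def test_log_score_tracks_linear_score(self):
        a = fp("a", np.linspace(5_000, 45_000, 12))
        b = fp("b", np.linspace(5_000, 45_000, 12))
        assert 10 ** pm.sulston_log10(a, b) == \
            pytest.approx(pm.sulston_score(a, b), rel=1e-6)


class TestBuildNet:
    def test_disjoint_fingerprints_edgeless(self):
        fps = [fp("a", [5_000, 6_000]), fp("b", [20_000, 21_000]),
               fp("c", [40_000, 41_000])]
        g = pm.build_net(fps, cutoff=1e-15)
        assert g.number_of_edges() == 0

    def test_cutoff_one_gives_complete_graph(self):
        fps = [fp("a", [5_000]), fp("b", [20_000]), fp("c", [40_000])]
        g = pm.build_net(fps, cutoff=1.0)
        assert g.number_of_edges() == 3

    def test_tiling_gives_connected_graph_matching_truth(self):
        fps, intervals = make_tiling_fingerprints(8, seed=4)
        g = pm.build_net(fps, cutoff=1e-25)
        for a, b in g.edges:
            (a0, a1), (b0, b1) = intervals[a], intervals[b]
            assert a0 < b1 and b0 < a1  # every edge is a true overlap
        assert nx.is_connected(g)


class TestLinearity:
    @staticmethod
    def graph(edges):
        g = nx.Graph()
        for a, b, score, shared in edges:
            g.add_edge(a, b, log10_score=score, shared=shared)
        return g

    def test_path_width_zero(self):
        g = self.graph([("a", "b", -40, 50), ("b", "c", -40, 50)])
        assert check_linearity(g) == 0

    def test_single_branch_width_one(self):
        g = self.graph([("a", "b", -40, 50), ("b", "c", -40, 50),
                        ("c", "d", -40, 50), ("c", "x", -39, 45)])
        assert check_linearity(g) <= 1

    def test_theta_graph_invalid(self):
        # three parallel two-edge paths between a and b: no single clone
        # removal linearises it
        g = self.graph([("a", "x", -40, 50), ("x", "b", -40, 50),
                        ("a", "y", -41, 50), ("y", "b", -41, 50),
                        ("a", "z", -42, 50), ("z", "b", -42, 50)])
        assert check_linearity(g) > 1

    def test_disconnected_rejected(self):
        g = self.graph([("a", "b", -40, 50)])
        g.add_node("zz")
        with pytest.raises(ValueError):
            check_linearity(g)

    def test_skeleton_drops_transitive_edge(self):
        g = self.graph([("a", "b", -50, 60), ("b", "c", -50, 60),
                        ("a", "c", -20, 30)])
        skel = _skeleton(g)
        assert not skel.has_edge("a", "c")
        assert _width_of_skeleton(skel) == 0


class TestConsensusBandMap:
    def test_identical_fingerprints_share_coordinate(self):
        bands = np.linspace(5_000, 45_000, 40)
        fps = [fp("a", bands), fp("b", bands)]
        order, cb = consensus_band_map(["a", "b"], fps)
        assert cb["a"] == 0.0 and cb["b"] == 0.0

    def test_new_bands_advance_coordinate(self):
        shared = np.linspace(5_000, 20_000, 60)
        new = np.linspace(30_000, 45_000, 4)
        a = fp("a", np.concatenate([shared, np.linspace(25_000, 28_000, 4)]))
        b = fp("b", np.concatenate([shared, new]))
        order, cb = consensus_band_map(["a", "b"], [a, b])
        # b has 4 bands not matched to a -> CB distance 4
        assert abs(cb["a"] - cb["b"]) == 4

    def test_renaming_preserves_cb_distances(self):
        fps, _ = make_tiling_fingerprints(5, seed=9)
        contig = [f.clone_id for f in fps]
        order, cb = consensus_band_map(contig, fps)
        renamed = [pm.Fingerprint(f"z{f.clone_id}", f.bands) for f in fps]
        order2, cb2 = consensus_band_map([f.clone_id for f in renamed],
                                         renamed)
        d1 = sorted(abs(cb[a] - cb[b])
                    for a, b in itertools.combinations(cb, 2))
        d2 = sorted(abs(cb2[a] - cb2[b])
                    for a, b in itertools.combinations(cb2, 2))
        assert d1 == d2


class TestAssembleContigs:
    def test_clean_tiling_single_contig(self):
        fps, intervals = make_tiling_fingerprints(10, seed=5)
        res = pm.assemble_contigs(fps)
        validated = [c for c in res.contigs if c.validated]
        assert len(validated) == 1
        contig = validated[0]
        assert len(contig) == 10 and contig.width == 0
        # recovered order is the physical order (or its reverse)
        truth_order = sorted(intervals, key=lambda c: intervals[c][0])
        assert contig.clones in (truth_order, truth_order[::-1])

    def test_chimeric_clone_removed_as_q(self):
        fps1, _ = make_tiling_fingerprints(6, seed=6)
        fps2, _ = make_tiling_fingerprints(6, seed=7)
        fps2 = [pm.Fingerprint("u" + f.clone_id, f.bands) for f in fps2]
        # chimera carries bands from the middle of both tilings
        chimera = pm.Fingerprint(
            "zchim", np.concatenate([fps1[3].bands[:60], fps2[3].bands[:60]]))
        res = pm.assemble_contigs(fps1 + fps2 + [chimera])
        validated = [c for c in res.contigs if c.validated]
        assert len(validated) == 2
        assert all("zchim" not in c.clones for c in validated)

    def test_too_few_clones_stay_unassembled(self):
        fps, _ = make_tiling_fingerprints(4, seed=8)
        res = pm.assemble_contigs(fps)
        assert [c for c in res.contigs if c.validated] == []
        assert sorted(res.unassembled) == sorted(f.clone_id for f in fps)

    def test_partition_invariant(self, clean_world):
        res = clean_world["assembly"]
        ids = [f.clone_id for f in clean_world["fps"]]
        seen = []
        for c in res.contigs:
            seen.extend(c.clones)
        seen.extend(res.unassembled)
        assert sorted(seen) == sorted(ids)

    def test_stricter_net_cutoff_no_more_false_joins(self, clean_world):
        """Lowering the subnet cut-off (more stringent) never increases
        the number of false adjacencies."""
        fps = clean_world["fps"]
        pos = {c.id: (c.start, c.end) for c in clean_world["clones"]}

        def false_joins(cutoff):
            params = AssemblyParams(subnet_cutoff=cutoff,
                                    strict_cutoff=min(cutoff, 1e-30))
            res = pm.assemble_contigs(fps, params)
            bad = 0
            for c in res.contigs:
                if not c.validated:
                    continue
                for a, b in zip(c.clones, c.clones[1:]):
                    (a0, a1), (b0, b1) = pos[a], pos[b]
                    bad += not (a0 < b1 and b0 < a1)
            return bad

        assert false_joins(1e-30) <= false_joins(1e-20)


class TestMTP:
    def test_single_clone_contig_kept(self):
        contig = pm.Contig(id="c1", clones=["a"], cb={"a": 0.0}, width=0,
                           validated=True)
        mtp, warns = pm.select_mtp([contig], [fp("a", [5_000])])
        assert mtp == ["a"] and warns == []

    def test_uniform_tiling_spans_contig(self, clean_world):
        validated = clean_world["validated"]
        fps = clean_world["fps"]
        mtp, _ = pm.select_mtp(validated, fps)
        fp_by_id = clean_world["fp_by_id"]
        for contig in validated:
            members = [c for c in contig.clones if c in mtp]
            assert members, f"contig {contig.id} lost from the MTP"
            ends = [contig.cb[c] + len(fp_by_id[c]) for c in members]
            span_end = max(contig.cb[c] + len(fp_by_id[c])
                           for c in contig.clones)
            assert max(ends) == span_end  # tiling reaches the contig end

    def test_unreachable_overlap_window_warns(self):
        # two clones overlapping by more than max_overlap
        shared = np.linspace(5_000, 45_000, 100)
        a = fp("a", shared)
        b = fp("b", np.concatenate([shared[5:], [46_000, 47_000, 48_000,
                                                 49_000, 49_500]]))
        contig = pm.Contig(id="c1", clones=["a", "b"],
                           cb={"a": 0.0, "b": 5.0}, width=0, validated=True)
        mtp, warns = pm.select_mtp([contig], [a, b],
                                   pm.MTPParams(min_overlap=30,
                                                max_overlap=60))
        assert set(mtp) == {"a", "b"}
        assert len(warns) == 1 and "gap risk" in warns[0]


class TestStats:
    def test_n50_l50_from_cumulative_definition(self):
        n50, l50 = n50_l50([5, 4, 3, 2, 1])
        assert (n50, l50) == (4, 2)

    def test_single_contig(self):
        n50, l50 = n50_l50([7])
        assert (n50, l50) == (7, 1)

    def test_coverage_can_exceed_one(self):
        contigs = [pm.Contig(id="c", clones=["x"], cb={}, width=0,
                             validated=True, cb_span=807_000.0)]
        st = pm.assembly_stats(contigs, 535_000.0, kb_per_cb=1.0)
        assert st.coverage_fraction == pytest.approx(1.51, abs=0.005)


class TestExhaustiveOracle:
    """Validated contig orders agree with an exhaustive consecutive-ones
    search over all clone orderings (small components)."""

    @staticmethod
    def consistent_orders(fps, params=None):
        g = pm.build_net(fps, params or AssemblyParams(), cutoff=1e-25)
        ids = [f.clone_id for f in fps]
        neighbours = {v: set(g[v]) for v in ids}
        orders = []
        for perm in itertools.permutations(ids):
            rank = {v: i for i, v in enumerate(perm)}
            ok = True
            for v in ids:
                ranks = sorted(rank[u] for u in neighbours[v] | {v})
                if ranks != list(range(ranks[0], ranks[0] + len(ranks))):
                    ok = False
                    break
            if ok:
                orders.append(list(perm))
        return orders

    @pytest.mark.parametrize("n_clones, seed", [(5, 21), (6, 22), (7, 23),
                                                (8, 24)])
    def test_contig_order_is_interval_consistent(self, n_clones, seed):
        fps, _ = make_tiling_fingerprints(n_clones, seed=seed)
        res = pm.assemble_contigs(fps)
        validated = [c for c in res.contigs if c.validated]
        assert len(validated) == 1
        oracle = self.consistent_orders(fps)
        assert validated[0].clones in oracle
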