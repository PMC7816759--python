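import itertools
import math

import networkx as nx
import numpy as np
import pytest

from domino_ami.engine import (DominoParams, RelevanceContext, compute_alpha,
                               build_pcst_instance, detect_relevant_slices,
                               hypergeom_tail, ng_partition,
                               propagate_influence, run_domino, slice_testable)
from domino_ami.fixtures import make_activity
from domino_ami.model_io import ActivityProfile, GeneNetwork
from domino_ami.slicer import SliceSet


def enum_hypergeom_tail(N, K, n, k):
    """Oracle: P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    hits = total = 0
    population = [1] * K + [0] * (N - K)
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


class TestAlphaAndTestability:
    def test_alpha_examples(self):
        assert compute_alpha(300, 3000) == pytest.approx(0.1 * (1 + 1 / 30))
        assert compute_alpha(3000, 3000) == 0.7
        assert compute_alpha(0, 3000) == 0.0

    def test_testable_by_active_share(self):
        ctx = RelevanceContext(300, 3000)
        slice_nodes = {f"g{i}" for i in range(100)}
        active = {f"g{i}" for i in range(30)} | {f"x{i}" for i in range(270)}
        assert slice_testable(slice_nodes, active, ctx)  # 30/300 >= 0.1

    def test_testable_by_internal_fraction(self):
        ctx = RelevanceContext(300, 3000)
        slice_nodes = {f"g{i}" for i in range(10)}
        active = {"g0", "g1"}  # 2/300 < 0.1 but 2/10 >= alpha ~ 0.10333
        assert slice_testable(slice_nodes, active, ctx)

    def test_untestable(self):
        ctx = RelevanceContext(300, 3000)
        slice_nodes = {f"g{i}" for i in range(50)}
        assert not slice_testable(slice_nodes, {"g0"}, ctx)

    def test_no_active_genes(self):
        ctx = RelevanceContext(0, 3000)
        assert not slice_testable({"g0", "g1"}, set(), ctx)


class TestHypergeomTail:
    def test_worked_examples(self):
        assert hypergeom_tail(10, 5, 3, 3) == pytest.approx(10 / 120)
        assert hypergeom_tail(4, 2, 2, 2) == pytest.approx(1 / 6)
        assert hypergeom_tail(10, 5, 3, 0) == 1.0

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            hypergeom_tail(10, 5, 3, 4)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 12, 3, 1)

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (12, 6, 5), (15, 7, 7)])
    def test_matches_enumeration(self, N, K, n):
        for k in range(0, min(K, n) + 1):
            assert hypergeom_tail(N, K, n, k) == pytest.approx(
                enum_hypergeom_tail(N, K, n, k)
            )


def _net_with_slices(n_background=3000):
    """A network of two testable 10-node slices embedded in a large node set."""
    g = nx.Graph()
    for s, prefix in enumerate(("s0_", "s1_")):
        nodes = [f"{prefix}{i}" for i in range(10)]
        g.add_edges_from(zip(nodes, nodes[1:]))
    for i in range(n_background):
        g.add_edge(f"bg{i}", f"bg{i}_b")
    return GeneNetwork(g)


class TestDetectRelevantSlices:
    def test_single_slice_kept(self):
        g = nx.path_graph([f"s{i}" for i in range(10)])
        g.add_edges_from((f"b{i}", f"b{i}x") for i in range(20))
        net = GeneNetwork(g)
        slices = SliceSet((frozenset(f"s{i}" for i in range(10)),))
        active = {"s0", "s1", "s2", "b0", "b1"}
        kept = detect_relevant_slices(slices, active, net)
        assert len(kept) == 1
        _s, p, q = kept[0]
        assert q == pytest.approx(p)  # single test: BH is identity
        assert q <= 0.3

    def test_bh_across_testable_slices(self):
        # engineered p-values: slice 0 is heavily active, slice 1 barely
        net = _net_with_slices(100)
        s0 = frozenset(f"s0_{i}" for i in range(10))
        s1 = frozenset(f"s1_{i}" for i in range(10))
        active = set(itertools.islice((n for n in sorted(net.nodes)), 0, 0))
        active = {f"s0_{i}" for i in range(8)} | {f"s1_{i}" for i in range(2)}
        kept = detect_relevant_slices(SliceSet((s0, s1)), active, net)
        kept_sets = {k[0] for k in kept}
        assert s0 in kept_sets
        for s, p, q in kept:
            assert q >= p

    def test_untestable_slice_never_kept(self):
        net = _net_with_slices(100)
        s0 = frozenset(f"s0_{i}" for i in range(10))
        # one active gene in the slice: below both testability conditions
        active = {"s0_0"} | {f"bg{i}" for i in range(30)}
        assert detect_relevant_slices(SliceSet((s0,)), active, net) == []


class TestPropagation:
    def test_path_double_influence(self):
        g = nx.path_graph(["a", "v", "b"])
        levels = propagate_influence(g, {"a", "b"})
        assert levels == {"a": 0, "b": 0, "v": 1}

    def test_star_blocks_low_influence(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        g = nx.relabel_nodes(g, {0: "v", 1: "u", 2: "w1", 3: "w2", 4: "w3"})
        levels = propagate_influence(g, {"u"})
        # u (degree 1) activates v with influence 1 > 0.5; v has degree 4 so
        # the remaining leaves receive only 0.25 and never activate
        assert levels == {"u": 0, "v": 1}

    def test_degree_four_neighbor_blocked(self):
        g = nx.star_graph(4)
        g = nx.relabel_nodes(g, {0: "hub", 1: "v", 2: "a", 3: "b", 4: "c"})
        levels = propagate_influence(g, {"hub"})
        assert levels == {"hub": 0}  # 1/4 <= 0.5 on every leaf

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_in_seeds(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(25, 0.15, seed=seed)
        nodes = sorted(g.nodes)
        seeds = set(rng.choice(nodes, size=5, replace=False).tolist())
        extra = seeds | set(rng.choice(nodes, size=3, replace=False).tolist())
        small = propagate_influence(g, seeds)
        big = propagate_influence(g, extra)
        for v, lvl in small.items():
            assert v in big and big[v] <= lvl


class TestPCSTInstance:
    def test_prize_decay(self):
        g = nx.path_graph(["a", "b", "c"])
        inst = build_pcst_instance(g, {"a"}, {"a": 0, "b": 1, "c": 2}, 300, 3000)
        assert inst.beta == pytest.approx(0.7)
        assert inst.prizes["a"] == 1.0
        assert inst.prizes["c"] == pytest.approx(0.49)

    def test_beta_floor_zero(self):
        g = nx.path_graph(["a", "b"])
        inst = build_pcst_instance(g, {"a"}, {"a": 0, "b": 1}, 1200, 3000)
        assert inst.beta == 0.0
        assert inst.prizes["b"] == 0.0

    def test_penalties(self):
        g = nx.path_graph(["a", "b", "c"])
        inst = build_pcst_instance(g, {"a"}, {"a": 0}, 300, 3000)
        assert inst.penalty("a", "b") == 0.0  # incident to the seed
        assert inst.penalty("b", "c") == pytest.approx(0.9999)


class TestNGPartition:
    @staticmethod
    def _two_cliques4():
        g = nx.Graph()
        a = [f"a{i}" for i in range(4)]
        b = [f"b{i}" for i in range(4)]
        g.add_edges_from(itertools.combinations(a, 2))
        g.add_edges_from(itertools.combinations(b, 2))
        g.add_edge("a0", "b0")
        return g, frozenset(a), frozenset(b)

    def test_bridge_removal_trace(self):
        g, a, b = self._two_cliques4()
        # threshold log(8)/log(1000) ~ 0.301; removing the bridge gives the
        # two-clique partition with modularity 12/13 - 1/2 ~ 0.4231 >= threshold
        assert math.log(8) / math.log(1000) == pytest.approx(0.3010, abs=1e-3)
        parts = ng_partition(g, 1000)
        assert set(parts) == {a, b}
        assert nx.community.modularity(g, [a, b]) == pytest.approx(12 / 13 - 0.5)

    def test_unreachable_threshold_singletons(self):
        g, _a, _b = self._two_cliques4()
        parts = ng_partition(g, g.number_of_nodes())  # threshold = 1
        assert all(len(p) == 1 for p in parts)
        assert len(parts) == 8


class TestRunDomino:
    def test_zero_active_empty_solution(self, planted, planted_slices):
        prof = ActivityProfile(planted.profile.table, activity_threshold=0.0)
        report = run_domino(planted.network, planted_slices, prof)
        assert report.modules == []

    def test_planted_recovery_and_invariants(self, planted, planted_slices):
        report = run_domino(planted.network, planted_slices, planted.profile)
        assert report.modules
        seen = set()
        n_putative = max(report.diagnostics["n_putative"], 1)
        for m in report.modules:
            assert nx.is_connected(planted.network.subgraph(m.nodes))
            assert not (m.nodes & seen)  # pairwise disjoint
            seen |= m.nodes
            assert m.q_value <= 0.05
            assert m.q_value == pytest.approx(min(1.0, m.p_value * n_putative))
        best = max(
            len(m.nodes & planted.planted[0]) / len(m.nodes | planted.planted[0])
            for m in report.modules
        )
        assert best >= 0.5

    def test_determinism_byte_identical(self, planted, planted_slices, tmp_path):
        import filecmp

        for d in ("r1", "r2"):
            run_domino(planted.network, planted_slices, planted.profile).write(
                tmp_path / d
            )
        assert filecmp.cmp(tmp_path / "r1" / "report.json",
                           tmp_path / "r2" / "report.json", shallow=False)
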