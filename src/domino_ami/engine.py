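"""Steps 1–3 of the module-discovery pipeline.

Given the cached slices, a run proceeds:

1. *Relevant slices* — slices passing a testability gate are tested for
   over-representation of active genes (hypergeometric tail, BH-corrected
   across testable slices, lenient q <= 0.3).
2. *Sub-slices* — within each relevant slice, activity is diffused with the
   linear-threshold model, prizes/penalties are derived, and a
   prize-collecting Steiner tree extracts the most active connected core.
3. *Putative and final modules* — large sub-slices not already
   over-represented are split with Girvan–Newman edge-betweenness
   partitioning under a modularity stopping rule; the resulting putative
   modules passing a strict Bonferroni-corrected over-representation test are
   reported as final modules.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
from scipy.stats import hypergeom

from .model_io import (ActivityProfile, GeneNetwork, Module, SolutionReport,
                       active_set, bh_qvalues)
from .pcst import PCSTInstance, solve_pcst
from .slicer import SliceSet

log = logging.getLogger(__name__)

__all__ = [
    "DominoParams",
    "RelevanceContext",
    "compute_alpha",
    "slice_testable",
    "hypergeom_tail",
    "detect_relevant_slices",
    "propagate_influence",
    "build_pcst_instance",
    "ng_partition",
    "run_domino",
]


@dataclass(frozen=True)
class DominoParams:
    """Pipeline parameters.  All threshold comparisons are inclusive (<=)."""

    theta: float = 0.5            # linear-threshold activation level
    epsilon: float = 1e-4         # penalised edges cost 1 - epsilon
    relevance_q: float = 0.3      # lenient FDR cutoff for relevant slices
    final_q: float = 0.05         # strict Bonferroni cutoff for final modules
    ng_max_size: int = 10         # sub-slices larger than this may be repartitioned
    midgate_p: float = 0.05       # raw-p over-representation gate before NG
    active_fraction_floor: float = 0.1  # slice testability, condition 1

    def __post_init__(self):
        if not (0 < self.relevance_q <= 1):
            raise ValueError("relevance_q must be in (0, 1]")
        if self.theta <= 0 or not (0 < self.epsilon < 1):
            raise ValueError("bad theta/epsilon")


@dataclass(frozen=True)
class RelevanceContext:
    """Network-wide counts driving slice testability."""

    n_active_network: int
    n_nodes_network: int

    @property
    def alpha(self) -> float:
        return compute_alpha(self.n_active_network, self.n_nodes_network)


def compute_alpha(n_active_network: int, n_nodes_network: int) -> float:
    """Minimum active fraction a slice must reach to be testable (capped at 0.7):
    alpha = min(0.7, (n_active/n_nodes) * (1 + 100/n_nodes))."""
    if n_nodes_network <= 0:
        raise ValueError("network must be nonempty")
    frac = n_active_network / n_nodes_network
    return min(0.7, frac * (1 + 100 / n_nodes_network))


def slice_testable(slice_nodes, active, ctx: RelevanceContext) -> bool:
    """A slice is tested only if it holds >= 10% of all active genes or its
    internal active fraction reaches alpha."""
    if ctx.n_active_network == 0:
        return False
    k = len(set(slice_nodes) & set(active))
    if k / ctx.n_active_network >= 0.1:
        return True
    return k / len(slice_nodes) >= ctx.alpha


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N population, K successes,
    n draws)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def detect_relevant_slices(
    slices: SliceSet,
    active,
    network: GeneNetwork,
    params: DominoParams | None = None,
):
    """Return ``[(slice_nodes, p, q), ...]`` for slices kept as relevant.

    Only testable slices enter the hypergeometric test (population = network
    nodes, successes = network active genes, draws = slice size); BH
    correction runs across the testable slices only, and slices with
    q <= relevance_q are kept.
    """
    params = params or DominoParams()
    active = frozenset(active) & network.nodes
    ctx = RelevanceContext(len(active), network.n_nodes)
    testable = [s for s in slices if slice_testable(s, active, ctx)]
    if not testable:
        return []
    pvals = [
        hypergeom_tail(network.n_nodes, len(active), len(s), len(s & active))
        for s in testable
    ]
    qvals = bh_qvalues(pvals)
    kept = [
        (s, p, float(q))
        for s, p, q in zip(testable, pvals, qvals)
        if q <= params.relevance_q
    ]
    kept.sort(key=lambda t: (t[2], -len(t[0]), min(t[0])))
    return kept


def propagate_influence(subgraph: nx.Graph, seeds, theta: float = 0.5) -> dict:
    """Linear-threshold influence propagation within one slice subgraph.

    Returns ``{node: activation_iteration}`` with 0 for the input-active
    seeds; a node joins at the first synchronous iteration where the summed
    influence 1/deg(u) of its already-active neighbours strictly exceeds
    *theta*.  Degrees are taken within the subgraph.  Nodes never activated
    are absent from the result.
    """
    seeds = set(seeds) & set(subgraph.nodes)
    level = {v: 0 for v in seeds}
    influence = {v: (1.0 / subgraph.degree(v)) if subgraph.degree(v) else 0.0
                 for v in subgraph.nodes}
    current = set(seeds)
    it = 0
    while True:
        it += 1
        newly = []
        for v in subgraph.nodes:
            if v in current:
                continue
            s = sum(influence[u] for u in subgraph.neighbors(v) if u in current)
            if s > theta:
                newly.append(v)
        if not newly:
            break
        for v in newly:
            level[v] = it
        current.update(newly)
    return level


def build_pcst_instance(
    subgraph: nx.Graph,
    seeds,
    propagation: dict,
    n_active_network: int,
    n_nodes_network: int,
    params: DominoParams | None = None,
) -> PCSTInstance:
    """Derive PCST prizes and penalties for one slice.

    beta = max(0, 1 - 3 * n_active_network / n_nodes_network); a node
    activated at iteration l gets prize beta^l (seeds therefore 1.0), nodes
    never activated get 0.  Edges incident to an input-active node cost 0,
    all others 1 - epsilon.
    """
    params = params or DominoParams()
    seeds = set(seeds) & set(subgraph.nodes)
    beta = max(0.0, 1.0 - 3.0 * n_active_network / n_nodes_network)
    prizes = {}
    for v in subgraph.nodes:
        lvl = propagation.get(v)
        if lvl is None:
            prizes[v] = 0.0
        elif lvl == 0:
            prizes[v] = 1.0
        else:
            prizes[v] = beta ** lvl
    penalties = {}
    for u, v in subgraph.edges:
        free = u in seeds or v in seeds
        penalties[frozenset((u, v))] = 0.0 if free else 1.0 - params.epsilon
    return PCSTInstance(subgraph, prizes, penalties, beta=beta)


def ng_partition(sub_slice_graph: nx.Graph, n_nodes_network: int):
    """Girvan–Newman repartition of a large sub-slice.

    Repeatedly removes the highest-edge-betweenness edge (recomputing
    betweenness after every removal; ties broken by lexicographic edge
    order), evaluating the modularity of the current connected-component
    partition on the ORIGINAL sub-slice graph; stops once
    log(|sub-slice|) / log(n_nodes_network) <= modularity, returning the
    current components.  If all edges are removed first, the singleton
    fallback is returned (logged).
    """
    n_sub = sub_slice_graph.number_of_nodes()
    if n_sub < 2 or n_nodes_network < 2:
        return [frozenset(sub_slice_graph.nodes)]
    threshold = math.log(n_sub) / math.log(n_nodes_network)
    work = sub_slice_graph.copy()
    while work.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(work)
        # tie-break: among max-betweenness edges take lexicographically smallest
        best = max(eb.values())
        cands = [tuple(sorted(e)) for e, b in eb.items() if abs(b - best) <= 1e-12]
        target = min(cands)
        work.remove_edge(*target)
        comps = [frozenset(c) for c in nx.connected_components(work)]
        m = nx.community.modularity(sub_slice_graph, comps)
        if threshold <= m:
            return sorted(comps, key=lambda c: (-len(c), min(c)))
    log.info("Girvan-Newman removed all edges without meeting the stopping "
             "criterion; returning singletons")
    return sorted(
        (frozenset((v,)) for v in sub_slice_graph.nodes), key=lambda c: min(c)
    )


def _overrep_p(nodes, active, network: GeneNetwork) -> tuple:
    k = len(set(nodes) & set(active))
    p = hypergeom_tail(network.n_nodes, len(active), len(nodes), k)
    return k, p


def run_domino(
    network: GeneNetwork,
    slices: SliceSet,
    profile: ActivityProfile,
    params: DominoParams | None = None,
) -> SolutionReport:
    """Run the full pipeline (steps 1–3) and return the solution report.

    Deterministic for a fixed input: every stage iterates nodes, slices and
    modules in a canonical order.
    """
    params = params or DominoParams()
    active = active_set(profile, network)
    diagnostics = {
        "n_nodes_network": network.n_nodes,
        "n_active_network": len(active),
        "n_slices": len(slices),
    }
    if not active:
        diagnostics.update(n_relevant_slices=0, n_putative=0)
        return SolutionReport([], diagnostics, params=vars(params).copy())

    relevant = detect_relevant_slices(slices, active, network, params)
    diagnostics["n_relevant_slices"] = len(relevant)

    sub_slices = []
    for slice_nodes, _p, _q in relevant:
        sub = network.subgraph(slice_nodes)
        seeds = active & slice_nodes
        prop = propagate_influence(sub, seeds, params.theta)
        inst = build_pcst_instance(
            sub, seeds, prop, len(active), network.n_nodes, params
        )
        picked = solve_pcst(inst)
        if picked:
            sub_slices.append(frozenset(picked))
    diagnostics["sub_slice_sizes"] = sorted((len(s) for s in sub_slices), reverse=True)

    putative = []
    for sub in sub_slices:
        if len(sub) > params.ng_max_size:
            _k, p = _overrep_p(sub, active, network)
            if p <= params.midgate_p:
                putative.append(sub)  # already over-represented: keep whole
            else:
                putative.extend(
                    ng_partition(network.subgraph(sub), network.n_nodes)
                )
        else:
            putative.append(sub)
    putative = sorted(set(putative), key=lambda s: (-len(s), min(s)))
    diagnostics["n_putative"] = len(putative)

    n_tests = max(len(putative), 1)
    final = []
    for nodes in putative:
        k, p = _overrep_p(nodes, active, network)
        q = min(1.0, p * n_tests)  # Bonferroni over the putative modules
        if q <= params.final_q:
            final.append(Module(nodes, "final", n_active=k, p_value=p, q_value=q))
    final.sort(key=lambda m: (m.q_value, -m.size, min(m.nodes)))
    diagnostics["n_final"] = len(final)
    return SolutionReport(final, diagnostics, params=vars(params).copy())
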