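"""Prize-collecting Steiner tree (PCST) solver used to refine slices.

The objective is the classic net-worth form: find a subtree T maximising
sum of node prizes in T minus sum of edge penalties on T's edges.  Prizes
come from linear-threshold influence propagation (decaying as beta^l with the
activation iteration l) and penalties are 0 for edges incident to an
input-active node and 1 - epsilon otherwise, so the solver mainly decides
which prize clusters are worth bridging across penalised edges.

Instances up to ``EXACT_MAX_NODES`` nodes are solved exactly by enumerating
connected node subsets with a bitmask search (the optimal tree on a fixed
node set is a minimum spanning tree of its induced subgraph).  Larger
instances use a heuristic: strong pruning of a minimum-penalty spanning tree,
rooted at every candidate node.  Strong pruning is exact on trees, so the
heuristic is exact whenever an optimal solution is a subtree of the MST —
which is typical here because the zero-penalty edges around active nodes are
always picked first by Kruskal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = ["PCSTInstance", "solve_pcst", "pcst_objective", "EXACT_MAX_NODES"]

EXACT_MAX_NODES = 13


@dataclass(frozen=True)
class PCSTInstance:
    """Node prizes and edge penalties over one (connected) slice subgraph."""

    graph: nx.Graph
    prizes: dict  # node -> prize >= 0
    penalties: dict  # frozenset({u, v}) -> penalty >= 0
    beta: float = 0.0

    def penalty(self, u, v) -> float:
        return self.penalties[frozenset((u, v))]


def _mst_edges(nodes, edges):
    """Kruskal MST over ``edges = [(cost, u, v), ...]``; deterministic under ties."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    picked = []
    total = 0.0
    for cost, u, v in sorted(edges):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            picked.append((u, v, cost))
            total += cost
    return picked, total


def pcst_objective(instance: PCSTInstance, nodes) -> float:
    """Objective of the best subtree spanning ``nodes`` (MST of the induced
    subgraph); -inf if the set does not induce a connected subgraph."""
    nodes = set(nodes)
    if not nodes:
        return 0.0
    sub = instance.graph.subgraph(nodes)
    if not nx.is_connected(sub):
        return float("-inf")
    edges = [(instance.penalty(u, v), min(u, v), max(u, v)) for u, v in sub.edges]
    _, cost = _mst_edges(nodes, edges)
    return sum(instance.prizes.get(n, 0.0) for n in nodes) - cost


def _solve_exact(instance: PCSTInstance) -> frozenset:
    """Enumerate connected node subsets via bitmasks (exact, <= EXACT_MAX_NODES)."""
    nodes = sorted(instance.graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    edge_list = []
    for u, v in instance.graph.edges:
        iu, iv = idx[u], idx[v]
        adj[iu] |= 1 << iv
        adj[iv] |= 1 << iu
        edge_list.append((iu, iv, instance.penalty(u, v)))
    prize = [instance.prizes.get(v, 0.0) for v in nodes]

    best_obj, best_mask = float("-inf"), 0
    for mask in range(1, 1 << n):
        # connectivity: BFS by bit expansion from the lowest set bit
        seed = mask & (-mask)
        reach = seed
        while True:
            frontier = 0
            m = reach
            while m:
                b = m & (-m)
                frontier |= adj[b.bit_length() - 1]
                m ^= b
            new = (reach | frontier) & mask
            if new == reach:
                break
            reach = new
        if reach != mask:
            continue
        obj = 0.0
        m = mask
        while m:
            b = m & (-m)
            obj += prize[b.bit_length() - 1]
            m ^= b
        k = bin(mask).count("1")
        if k > 1:
            in_mask = [(c, iu, iv) for iu, iv, c in edge_list
                       if (mask >> iu) & 1 and (mask >> iv) & 1]
            _, cost = _mst_edges(
                [i for i in range(n) if (mask >> i) & 1],
                [(c, a, b) for c, a, b in in_mask],
            )
            obj -= cost
        if obj > best_obj + 1e-12 or (
            abs(obj - best_obj) <= 1e-12 and mask < best_mask
        ):
            best_obj, best_mask = obj, mask
    return frozenset(nodes[i] for i in range(n) if (best_mask >> i) & 1)


def _strong_prune(tree_adj, prizes, root):
    """Exact PCST on a tree rooted at ``root``: returns (value, node set)."""
    # iterative post-order
    order, stack, parent = [], [root], {root: None}
    while stack:
        v = stack.pop()
        order.append(v)
        for u, _c in tree_adj[v]:
            if u != parent[v]:
                parent[u] = v
                stack.append(u)
    net = {}
    keep_child = {v: [] for v in order}
    for v in reversed(order):
        val = prizes.get(v, 0.0)
        for u, c in tree_adj[v]:
            if parent.get(u) == v:
                margin = net[u] - c
                if margin > 1e-15:
                    val += margin
                    keep_child[v].append(u)
        net[v] = val
    kept, stack = {root}, [root]
    while stack:
        v = stack.pop()
        for u in keep_child[v]:
            kept.add(u)
            stack.append(u)
    return net[root], kept


def _solve_heuristic(instance: PCSTInstance) -> frozenset:
    nodes = sorted(instance.graph.nodes)
    edges = [(instance.penalty(u, v), min(u, v), max(u, v))
             for u, v in instance.graph.edges]
    mst, _ = _mst_edges(nodes, edges)
    tree_adj = {v: [] for v in nodes}
    for u, v, c in mst:
        tree_adj[u].append((v, c))
        tree_adj[v].append((u, c))
    # roots: all prized nodes, plus a fallback node; cap for very large slices
    roots = [v for v in nodes if instance.prizes.get(v, 0.0) > 0]
    if not roots:
        roots = [nodes[0]]
    if len(nodes) > 800:
        roots = sorted(roots, key=lambda v: -instance.prizes.get(v, 0.0))[:200]
    best_val, best_set = float("-inf"), frozenset()
    for r in roots:
        val, kept = _strong_prune(tree_adj, instance.prizes, r)
        if val > best_val + 1e-12 or (
            abs(val - best_val) <= 1e-12 and sorted(kept) < sorted(best_set)
        ):
            best_val, best_set = val, frozenset(kept)
    return best_set


def solve_pcst(instance: PCSTInstance, exact_max_nodes: int = EXACT_MAX_NODES) -> frozenset:
    """Solve the PCST instance, returning the connected node set of the best
    subtree found (at least the best single node)."""
    n = instance.graph.number_of_nodes()
    if n == 0:
        return frozenset()
    if n <= exact_max_nodes:
        return _solve_exact(instance)
    return _solve_heuristic(instance)
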