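"""Seeded synthetic generators: planted-community networks, planted active
gene sets, and toy ontologies with aligned annotations.

The generators emulate the three external inputs (interaction network,
activity score table, ontology + annotations) so the whole pipeline is
testable without downloads.  The default planted world: a 500-node
stochastic-block-model network of 25 communities of 20 genes each
(p_in = 0.3, p_out = 0.002, giving average degree around 6 — sparse, like a
curated PPI network), one planted community in which 80% of genes carry a
significant activity score (q drawn uniformly below 0.01), a 5% uniform
background active rate, and a toy BP-like DAG with one leaf term per
community annotated to its genes.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .go_enrichment import OntologyIndex, build_index
from .model_io import ActivityProfile, GeneNetwork, write_activity, write_network

log = logging.getLogger(__name__)

__all__ = [
    "PlantedFixture",
    "make_network",
    "make_activity",
    "make_ontology",
    "planted_default",
    "null_fixture",
]

_RETRY_BOUND = 20
ROOT_TERM = "TOY:0000000"


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def make_network(
    n_nodes: int = 500,
    n_communities: int = 25,
    p_in: float = 0.3,
    p_out: float = 0.002,
    seed: int = 42,
):
    """Stochastic-block-model network with synthetic gene ids.

    Returns ``(GeneNetwork, labels)`` with ``labels[gene] = community index``.
    Every community's induced subgraph must be connected (communities are the
    planting candidates); disconnected draws are regenerated up to a retry
    bound, then an error is raised.
    """
    if p_in <= p_out:
        raise ValueError("p_in must exceed p_out")
    base = n_nodes // n_communities
    sizes = [base] * n_communities
    sizes[-1] += n_nodes - base * n_communities
    probs = [
        [p_in if i == j else p_out for j in range(n_communities)]
        for i in range(n_communities)
    ]
    for attempt in range(_RETRY_BOUND):
        sbm_seed = int(np.random.SeedSequence(seed, spawn_key=(attempt,))
                       .generate_state(1)[0] % (2**31))
        g = nx.stochastic_block_model(sizes, probs, seed=sbm_seed)
        mapping = {i: _gene_id(i) for i in g.nodes}
        labels = {mapping[i]: g.nodes[i]["block"] for i in g.nodes}
        g = nx.relabel_nodes(g, mapping)
        g.graph.clear()
        ok = True
        for c in range(n_communities):
            members = [v for v, b in labels.items() if b == c]
            if len(members) > 3 and not nx.is_connected(g.subgraph(members)):
                ok = False
                break
        if ok:
            return GeneNetwork(nx.Graph(g)), labels
    raise RuntimeError(
        f"could not draw an SBM with connected communities in {_RETRY_BOUND} tries"
    )


def make_activity(
    network: GeneNetwork,
    planted,
    q_active_max: float = 0.01,
    signal_rate: float = 0.8,
    seed: int = 42,
) -> ActivityProfile:
    """Activity profile with planted signal.

    Genes in the planted sets draw q ~ Uniform(0, q_active_max) with
    probability *signal_rate*; all other draws are q ~ Uniform(0, 1) (so the
    background active rate at threshold 0.05 is about 5%).  p is set equal to
    q: the fixture states calibrated q-values directly rather than re-deriving
    BH inside the generator.
    """
    rng = np.random.default_rng(seed)
    planted_genes = frozenset().union(*planted) if planted else frozenset()
    genes = sorted(network.nodes)
    q = np.empty(len(genes))
    for i, gene in enumerate(genes):
        if gene in planted_genes and rng.random() < signal_rate:
            q[i] = rng.uniform(0, q_active_max)
        else:
            q[i] = rng.uniform(0, 1)
    table = pd.DataFrame({"pval": q, "qval": q}, index=pd.Index(genes, name="gene"))
    return ActivityProfile(table)


def make_ontology(
    labels: dict,
    n_terms_per_community: int = 1,
    n_background_terms: int = 10,
    seed: int = 42,
    coverage: float = 0.9,
    n_noise_genes: int = 2,
):
    """Toy BP-like DAG aligned with the network's community structure.

    Structure: one root, one mid-level branch term per community, and
    *n_terms_per_community* leaf terms per community annotated to a
    *coverage* fraction of the community's genes plus a few random noise
    genes; *n_background_terms* extra leaves annotated to random gene sets.
    All leaf terms satisfy the 5-500 gene filter by construction.

    Returns ``(OntologyIndex, community_terms, obo_records, gaf_pairs)``
    where ``community_terms[c]`` lists the leaf terms aligned with community
    ``c`` and the last two items allow writing OBO/GAF text files.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(labels)
    communities = sorted(set(labels.values()))
    parent_map = {ROOT_TERM: []}
    direct = {ROOT_TERM: set(genes)}
    community_terms = {}
    next_id = 1

    def new_term(parents):
        nonlocal next_id
        tid = f"TOY:{next_id:07d}"
        next_id += 1
        parent_map[tid] = list(parents)
        direct[tid] = set()
        return tid

    for c in communities:
        members = [g for g in genes if labels[g] == c]
        branch = new_term([ROOT_TERM])
        community_terms[c] = []
        for _ in range(n_terms_per_community):
            leaf = new_term([branch])
            n_keep = max(5, int(round(coverage * len(members))))
            keep = list(rng.choice(members, size=min(n_keep, len(members)),
                                   replace=False))
            noise = list(rng.choice(genes, size=n_noise_genes, replace=False))
            direct[leaf] = set(keep) | set(noise)
            community_terms[c].append(leaf)
    bg_branch = new_term([ROOT_TERM])
    for _ in range(n_background_terms):
        leaf = new_term([bg_branch])
        size = int(rng.integers(8, 40))
        direct[leaf] = set(rng.choice(genes, size=size, replace=False))

    index = build_index(parent_map, direct)
    gaf_pairs = sorted(
        (g, t) for t, gs in direct.items() for g in gs if t != ROOT_TERM
    )
    # root membership comes from propagation in real corpora; annotate the
    # root directly only in the index so IC(root) = 0 holds regardless
    obo_records = {t: parent_map[t] for t in parent_map}
    return index, community_terms, obo_records, gaf_pairs


@dataclass
class PlantedFixture:
    """A complete synthetic world plus its ground truth."""

    network: GeneNetwork
    labels: dict
    planted: list                  # list of frozensets of gene ids
    profile: ActivityProfile
    index: OntologyIndex
    truth_terms: list              # terms expected to be enriched/EV
    obo_records: dict = field(default_factory=dict)
    gaf_pairs: list = field(default_factory=list)
    seed: int = 42

    def write(self, out_dir) -> None:
        """Export network.tsv, scores.tsv, toy.obo, toy.gaf and truth.json."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_network(self.network, out_dir / "network.tsv")
        write_activity(self.profile, out_dir / "scores.tsv")
        with open(out_dir / "toy.obo", "w", encoding="utf-8") as fh:
            fh.write("format-version: 1.2\n")
            for tid in sorted(self.obo_records):
                fh.write(f"\n[Term]\nid: {tid}\nname: {tid}\n"
                         "namespace: biological_process\n")
                for parent in self.obo_records[tid]:
                    fh.write(f"is_a: {parent}\n")
        with open(out_dir / "toy.gaf", "w", encoding="utf-8") as fh:
            fh.write("!gaf-version: 2.1\n")
            for gene, term in self.gaf_pairs:
                cols = ["TOY", gene, gene, "", term, "TOY:ref", "IDA", "",
                        "P", gene, "", "protein", "taxon:0000", "20200101", "TOY",
                        "", ""]
                fh.write("\t".join(cols) + "\n")
        with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "planted": [sorted(s) for s in self.planted],
                    "truth_terms": sorted(self.truth_terms),
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


def planted_default(seed: int = 42) -> PlantedFixture:
    """The default planted world (see module docstring)."""
    network, labels = make_network(seed=seed)
    planted_c = 0
    planted = [frozenset(g for g, b in labels.items() if b == planted_c)]
    profile = make_activity(network, planted, seed=seed + 1)
    index, community_terms, obo_records, gaf_pairs = make_ontology(labels, seed=seed + 2)
    return PlantedFixture(
        network, labels, planted, profile, index,
        truth_terms=list(community_terms[planted_c]),
        obo_records=obo_records, gaf_pairs=gaf_pairs, seed=seed,
    )


def null_fixture(seed: int = 42, n_nodes: int = 500) -> PlantedFixture:
    """Same world, no planted signal: scores are pure Uniform(0, 1) noise."""
    network, labels = make_network(n_nodes=n_nodes,
                                   n_communities=max(2, n_nodes // 20), seed=seed)
    profile = make_activity(network, [], seed=seed + 1)
    index, community_terms, obo_records, gaf_pairs = make_ontology(labels, seed=seed + 2)
    return PlantedFixture(
        network, labels, [], profile, index, truth_terms=[],
        obo_records=obo_records, gaf_pairs=gaf_pairs, seed=seed,
    )
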