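"""GO Biological Process enrichment of modules with the network as background.

The ontology index holds the BP term DAG (is_a, and optionally part_of,
edges), per-term annotated gene sets after evidence-code exclusion and
ancestral up-propagation, and per-term information content
IC(t) = -ln(freq(t)) used for Resnik semantic similarity.  Only terms
annotating 5–500 genes (over the full corpus, post-exclusion and
post-propagation) are usable for enrichment.

Annotations derived from physical interaction, expression pattern, genetic
interaction or mutant phenotype are excluded by default (evidence codes IPI,
IEP, IGI, IMP, HMP, HGI, HEP) because they could be confounded with the very
network and activity data being analysed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .engine import hypergeom_tail
from .model_io import _open_text, bh_qvalues

log = logging.getLogger(__name__)

__all__ = [
    "OntologyIndex",
    "EnrichmentRecord",
    "DEFAULT_EXCLUDED_CODES",
    "MIN_TERM_GENES",
    "MAX_TERM_GENES",
    "load_ontology",
    "build_index",
    "module_enrichment",
    "solution_term_scores",
]

DEFAULT_EXCLUDED_CODES = frozenset(
    {"IPI", "IEP", "IGI", "IMP", "HMP", "HGI", "HEP"}
)
MIN_TERM_GENES = 5
MAX_TERM_GENES = 500


@dataclass
class OntologyIndex:
    """BP term DAG plus propagated gene annotations and information content."""

    dag: nx.DiGraph                      # edges child -> parent
    term_genes: dict                     # term -> frozenset of gene ids (propagated)
    usable_terms: tuple = ()             # terms passing the 5-500 size filter
    _ancestor_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("ontology graph is cyclic")
        self.n_corpus_genes = len(
            frozenset().union(*self.term_genes.values()) if self.term_genes else frozenset()
        )
        if not self.usable_terms:
            self.usable_terms = tuple(sorted(
                t for t, genes in self.term_genes.items()
                if MIN_TERM_GENES <= len(genes) <= MAX_TERM_GENES
            ))

    def ancestors(self, term) -> frozenset:
        """All ancestors of *term* in the DAG, including the term itself."""
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.dag, term)) | {term}
            self._ancestor_cache[term] = cached
        return cached

    def ic(self, term) -> float:
        """Information content -ln(n_genes(term) / n_corpus_genes), in nats."""
        genes = self.term_genes.get(term, frozenset())
        if not genes or self.n_corpus_genes == 0:
            return 0.0
        return -math.log(len(genes) / self.n_corpus_genes)


def _parse_obo(path):
    """Minimal OBO 1.2 reader: id, namespace, is_a, relationship part_of,
    is_obsolete per [Term] stanza."""
    terms, current, in_term = [], None, False
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                if current is not None:
                    terms.append(current)
                in_term = line == "[Term]"
                current = {"is_a": [], "part_of": []} if in_term else None
                continue
            if not in_term or not line or ":" not in line:
                continue
            key, val = line.split(":", 1)
            val = val.strip()
            if key == "id":
                current["id"] = val
            elif key == "namespace":
                current["namespace"] = val
            elif key == "is_a":
                current["is_a"].append(val.split("!")[0].strip())
            elif key == "relationship" and val.startswith("part_of"):
                current["part_of"].append(val.split("part_of", 1)[1].split("!")[0].strip())
            elif key == "is_obsolete":
                current["obsolete"] = val.lower().startswith("true")
    if current is not None:
        terms.append(current)
    return [t for t in terms if "id" in t and not t.get("obsolete")]


def _parse_gaf(path, excluded_codes, gene_column: int = 2):
    """Minimal GAF 2.x reader yielding (gene, term) for BP annotations.

    Skips comment lines, NOT-qualified lines, excluded evidence codes and
    non-P aspects.  *gene_column* is the 0-based column holding the gene id
    (default 2 = DB Object Symbol).
    """
    pairs = []
    with _open_text(path) as fh:
        for raw in fh:
            if raw.startswith("!") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            qualifier, term, evidence, aspect = cols[3], cols[4], cols[6], cols[8]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence in excluded_codes:
                continue
            if aspect != "P":
                continue
            pairs.append((cols[gene_column], term))
    return pairs


def load_ontology(
    obo_path,
    gaf_path,
    excluded_codes=DEFAULT_EXCLUDED_CODES,
    include_part_of: bool = True,
    gene_column: int = 2,
) -> OntologyIndex:
    """Build an :class:`OntologyIndex` from an OBO file and a GAF file.

    Keeps only biological_process terms, drops NOT-qualified and
    excluded-evidence annotation lines, up-propagates gene sets along is_a
    (and, by default, part_of) edges within BP, then applies the 5–500 term
    size filter to define the usable terms.
    """
    terms = _parse_obo(obo_path)
    namespaces = {t.get("namespace") for t in terms}
    if namespaces == {None}:
        raise ValueError(f"{obo_path}: no namespace declarations found")
    bp = {t["id"]: t for t in terms if t.get("namespace") == "biological_process"}
    parent_map = {
        tid: list(t["is_a"]) + (list(t["part_of"]) if include_part_of else [])
        for tid, t in bp.items()
    }
    direct = {tid: set() for tid in bp}
    n_lines = 0
    for gene, term in _parse_gaf(gaf_path, frozenset(excluded_codes), gene_column):
        n_lines += 1
        if term in direct:
            direct[term].add(gene)
    index = build_index(parent_map, direct)
    log.info(
        "ontology: %d BP terms, %d usable (5-500 genes), %d annotation lines kept",
        len(bp), len(index.usable_terms), n_lines,
    )
    return index


def build_index(parent_map: dict, direct_annotations: dict) -> OntologyIndex:
    """Assemble an :class:`OntologyIndex` from ``{term: [parent terms]}`` and
    ``{term: set of directly annotated genes}`` (up-propagation included)."""
    dag = nx.DiGraph()
    dag.add_nodes_from(parent_map)
    for tid, parents in parent_map.items():
        for parent in parents:
            if parent in parent_map:
                dag.add_edge(tid, parent)
    term_genes = {tid: set(direct_annotations.get(tid, ())) for tid in parent_map}
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("ontology graph is cyclic")
    # child -> parent edges: topological order visits children before parents
    for tid in nx.topological_sort(dag):
        for parent in dag.successors(tid):
            term_genes[parent] |= term_genes[tid]
    return OntologyIndex(dag, {t: frozenset(g) for t, g in term_genes.items()})


@dataclass(frozen=True)
class EnrichmentRecord:
    """Hypergeometric over-representation of one GO term in one module."""

    term: str
    module_id: int
    p_value: float
    q_value: float

    @property
    def score(self) -> float:
        """Enrichment score -log10(p)."""
        return -math.log10(max(self.p_value, 1e-300))


def module_enrichment(module, index: OntologyIndex, background, module_id: int = 0) -> list:
    """Enrichment records for one module over all usable terms.

    Hypergeometric tail with population = background (network genes),
    successes = term genes on the background, draws = the module; BH
    correction across terms within the module; sorted by p (ties by term id).
    Terms with zero module overlap are included with p = 1 so downstream
    permutation nulls are defined for every usable term.
    """
    module = frozenset(module) & frozenset(background)
    if not module:
        return []
    background = frozenset(background)
    N, n = len(background), len(module)
    terms, pvals = [], []
    for t in index.usable_terms:
        genes_on_bg = index.term_genes[t] & background
        K = len(genes_on_bg)
        k = len(genes_on_bg & module)
        terms.append(t)
        pvals.append(hypergeom_tail(N, K, n, k) if K else 1.0)
    qvals = bh_qvalues(pvals)
    records = [
        EnrichmentRecord(t, module_id, float(p), float(q))
        for t, p, q in zip(terms, pvals, qvals)
    ]
    records.sort(key=lambda r: (r.p_value, r.term))
    return records


def solution_term_scores(per_module_records) -> dict:
    """Collapse per-module enrichment to per-term best results.

    Returns ``{term: (score, best_q, best_p)}`` where score is the maximal
    -log10(p) over the solution's modules; terms absent from every module's
    records score 0 by convention.
    """
    best = {}
    for records in per_module_records:
        for r in records:
            cur = best.get(r.term)
            if cur is None or r.p_value < cur[2]:
                best[r.term] = (r.score, r.q_value, r.p_value)
    return best
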