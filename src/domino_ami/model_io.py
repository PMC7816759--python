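"""Core domain types and I/O: gene networks, activity-score tables, modules.

Gene identifiers are opaque strings throughout; no namespace mapping is ever
attempted.  The network, the score table and the GO annotation must share one
identifier namespace — a mismatch shows up as a logged overlap statistic, not
an error.
"""
from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "ActivityProfile",
    "Module",
    "SolutionReport",
    "NetworkFormatError",
    "ActivityValidationError",
    "read_network",
    "write_network",
    "read_activity",
    "write_activity",
    "active_set",
    "bh_qvalues",
]


class NetworkFormatError(ValueError):
    """Raised for malformed network files (message names the line number)."""


class ActivityValidationError(ValueError):
    """Raised when activity scores fall outside [0, 1] or the table is malformed."""


def _open_text(path):
    """Open ``path`` for text reading, transparently decompressing gzip."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def bh_qvalues(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values (FDR) for an array of p-values."""
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# GeneNetwork


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected gene interaction network; the background for all statistics.

    Invariants: no self-loops, no duplicate edges regardless of orientation,
    every edge endpoint is a node.  Edge weights (confidence scores) are kept
    only if present in the source file; all algorithms treat the graph as
    unweighted.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> frozenset:
        return frozenset(frozenset(e) for e in self.graph.edges)

    def subgraph(self, nodes: Iterable[str]) -> nx.Graph:
        """Induced subgraph (a plain networkx view copy)."""
        return self.graph.subgraph(nodes).copy()

    def fingerprint(self) -> str:
        """Stable SHA-1 of the sorted node and edge lists."""
        h = hashlib.sha1()
        for n in sorted(self.graph.nodes):
            h.update(n.encode())
            h.update(b"\n")
        h.update(b"--\n")
        for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
            h.update(f"{u}\t{v}\n".encode())
        return h.hexdigest()


def read_network(path, min_edge_weight: float | None = None) -> GeneNetwork:
    """Read a 2/3-column delimited edge list (SIF dialect accepted) into a
    :class:`GeneNetwork`.

    Three-column lines are interpreted as ``a b weight`` when the third field
    parses as a number, and as SIF ``a interaction b`` otherwise.  Self-loops
    are dropped and edges deduplicated regardless of orientation.  When
    *min_edge_weight* is given, weighted edges with weight <= the threshold
    are removed before deduplication (strict ``>`` retained); unweighted
    lines are unaffected by the filter.
    """
    g = nx.Graph()
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 2:
                a, b = parts
                w = None
            elif len(parts) == 3:
                a, mid, c = parts
                try:
                    w = float(c)
                    b = mid
                except ValueError:
                    # SIF dialect: a <interaction-type> b
                    a, b, w = a, c, None
            else:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: expected 2 or 3 fields, got {len(parts)}"
                )
            if not a or not b:
                raise NetworkFormatError(f"{path}: line {lineno}: empty gene id")
            if a == b:
                continue  # self-loop
            if min_edge_weight is not None and w is not None and w <= min_edge_weight:
                continue
            if g.has_edge(a, b):
                old = g[a][b].get("weight")
                if w is not None and (old is None or w > old):
                    g[a][b]["weight"] = w
            else:
                if w is None:
                    g.add_edge(a, b)
                else:
                    g.add_edge(a, b, weight=w)
    if g.number_of_nodes() == 0:
        raise NetworkFormatError(f"{path}: no edges parsed; empty network")
    return GeneNetwork(g)


def write_network(network: GeneNetwork, path) -> None:
    """Write the network as a sorted TSV edge list (weight column if present)."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
            w = network.graph[u][v].get("weight")
            if w is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{w:g}\n")


# ---------------------------------------------------------------------------
# ActivityProfile


@dataclass
class ActivityProfile:
    """Per-gene activity scores (p-value and BH q-value).

    ``table`` is indexed by gene id with float columns ``pval`` and ``qval``.
    The binary active-gene set is induced by ``qval <= activity_threshold``
    (inclusive boundary, uniformly across the package).
    """

    table: pd.DataFrame
    activity_threshold: float = 0.05

    def __post_init__(self):
        for col in ("pval", "qval"):
            vals = self.table[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 1)) or np.any(np.isnan(vals)):
                raise ActivityValidationError(f"{col} outside [0, 1]")
        bad = int((self.table["qval"] < self.table["pval"] - 1e-12).sum())
        if bad:
            log.warning("%d genes have qval < pval; q-values look inconsistent", bad)

    @property
    def genes(self) -> frozenset:
        return frozenset(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_pvalues(cls, pvals: dict, activity_threshold: float = 0.05) -> "ActivityProfile":
        """Build a profile from raw p-values, deriving BH q-values."""
        genes = list(pvals)
        p = np.asarray([pvals[g] for g in genes], dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ActivityValidationError("p-value outside [0, 1]")
        q = bh_qvalues(p)
        table = pd.DataFrame({"pval": p, "qval": q}, index=pd.Index(genes, name="gene"))
        return cls(table, activity_threshold)


def read_activity(path, activity_threshold: float = 0.05) -> ActivityProfile:
    """Read a headed TSV score table ``gene<TAB>pval[<TAB>qval]``.

    If the q-value column is absent, BH q-values are computed over all listed
    genes.  Scores outside [0, 1] raise :class:`ActivityValidationError`.
    """
    df = pd.read_csv(_open_text(path), sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    rename = {"pvalue": "pval", "p": "pval", "qvalue": "qval", "q": "qval", "id": "gene"}
    df = df.rename(columns=rename)
    if "gene" not in df.columns or "pval" not in df.columns:
        raise ActivityValidationError(f"{path}: need columns 'gene' and 'pval'")
    df = df.set_index("gene")
    p = df["pval"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ActivityValidationError(f"{path}: p-value outside [0, 1]")
    if "qval" in df.columns:
        q = df["qval"].to_numpy(dtype=float)
    else:
        q = bh_qvalues(p)
    table = pd.DataFrame({"pval": p, "qval": q}, index=df.index)
    return ActivityProfile(table, activity_threshold)


def write_activity(profile: ActivityProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tpval\tqval\n")
        for gene, row in profile.table.iterrows():
            fh.write(f"{gene}\t{row['pval']:.8g}\t{row['qval']:.8g}\n")


def active_set(profile: ActivityProfile, network: GeneNetwork) -> frozenset:
    """Genes with q-value <= the activity threshold, restricted to the network.

    Scored genes absent from the network are dropped here (with a logged
    count) but remain in the profile for score permutation.
    """
    q = profile.table["qval"]
    active = frozenset(q.index[q <= profile.activity_threshold])
    on_net = active & network.nodes
    off_net_scored = len(profile.genes - network.nodes)
    if off_net_scored:
        log.info(
            "%d of %d scored genes are absent from the network (%d of them active)",
            off_net_scored, len(profile), len(active) - len(on_net),
        )
    return on_net


# ---------------------------------------------------------------------------
# Modules and solutions


@dataclass(frozen=True)
class Module:
    """A node set with pipeline provenance and over-representation diagnostics."""

    nodes: frozenset
    stage: str  # slice | sub_slice | putative | final
    n_active: int = 0
    p_value: float = 1.0
    q_value: float = 1.0

    @property
    def size(self) -> int:
        return len(self.nodes)

    def sorted_nodes(self) -> list:
        return sorted(self.nodes)


@dataclass
class SolutionReport:
    """Final modules of one run plus per-stage diagnostics."""

    modules: list
    diagnostics: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "modules": [
                {
                    "genes": m.sorted_nodes(),
                    "size": m.size,
                    "n_active": m.n_active,
                    "p_value": m.p_value,
                    "q_value": m.q_value,
                }
                for m in self.modules
            ],
            "diagnostics": self.diagnostics,
            "params": self.params,
        }

    def write(self, out_dir) -> None:
        """Write ``modules.txt`` (one module per line, tab-separated gene ids)
        and ``report.json`` under *out_dir*."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "modules.txt", "w", encoding="utf-8") as fh:
            for m in self.modules:
                fh.write("\t".join(m.sorted_nodes()) + "\n")
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_modules(path) -> list:
    """Read a modules.txt file back into a list of frozensets."""
    modules = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                modules.append(frozenset(line.split("\t")))
    return modules
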