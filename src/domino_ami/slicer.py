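"""Step 0 — one-time partitioning of the network into disjoint slices.

Slices are connected, highly intra-connected node sets obtained by Louvain
community detection at a low resolution (default r = 0.15, which favours
coarse communities), keeping only connected components with more than three
nodes.  Slicing depends only on the network topology, so the result is cached
to a text file and reused for every analysed dataset.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .model_io import GeneNetwork, _open_text

log = logging.getLogger(__name__)

__all__ = ["SlicerParams", "SliceSet", "build_slices", "write_slices", "read_slices"]

MIN_SLICE_SIZE = 4  # "more than three nodes"


@dataclass(frozen=True)
class SlicerParams:
    resolution: float = 0.15
    min_slice_size: int = MIN_SLICE_SIZE
    seed: int = 42

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass(frozen=True)
class SliceSet:
    """Pairwise-disjoint connected slices plus the source-network fingerprint."""

    slices: tuple  # tuple of frozensets
    fingerprint: str = ""
    seed: int = 0
    resolution: float = 0.15

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)


def build_slices(network: GeneNetwork, params: SlicerParams | None = None) -> SliceSet:
    """Partition the network into slices.

    Runs resolution-parameterised Louvain (the modularity-gain variant where
    the expected-edge term is scaled by r), then decomposes each community's
    induced subgraph into connected components; components with more than
    three nodes become slices.  The graph is treated as unweighted even if
    edge weights were read.
    """
    params = params or SlicerParams()
    g = network.graph
    # strip weights so Louvain matches the unweighted usage
    communities = nx.community.louvain_communities(
        g, weight=None, resolution=params.resolution, seed=params.seed
    )
    slices = []
    for comm in communities:
        sub = g.subgraph(comm)
        for comp in nx.connected_components(sub):
            if len(comp) >= params.min_slice_size:
                slices.append(frozenset(comp))
    if not slices:
        log.warning("slicer produced zero slices (all components <= 3 nodes)")
    # deterministic order: big slices first, ties by smallest member id
    slices.sort(key=lambda s: (-len(s), min(s)))
    return SliceSet(
        slices=tuple(slices),
        fingerprint=network.fingerprint(),
        seed=params.seed,
        resolution=params.resolution,
    )


def write_slices(slice_set: SliceSet, path) -> None:
    """Write the slice cache: header lines then one slice per line (TSV ids)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#network_fingerprint={slice_set.fingerprint}\n")
        fh.write(f"#seed={slice_set.seed}\n")
        fh.write(f"#resolution={slice_set.resolution:g}\n")
        for s in slice_set.slices:
            fh.write("\t".join(sorted(s)) + "\n")


def read_slices(path, network: GeneNetwork | None = None) -> SliceSet:
    """Read a slice cache file; warn if it does not match *network*."""
    fingerprint, seed, resolution = "", 0, 0.15
    slices = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, val = line[1:].split("=", 1)
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: bad header") from exc
                if key == "network_fingerprint":
                    fingerprint = val
                elif key == "seed":
                    seed = int(val)
                elif key == "resolution":
                    resolution = float(val)
                continue
            ids = [x for x in line.split("\t") if x]
            if not ids:
                raise ValueError(f"{path}: line {lineno}: empty slice line")
            slices.append(frozenset(ids))
    if network is not None and fingerprint and fingerprint != network.fingerprint():
        log.warning(
            "slice cache %s was built for a different network (fingerprint mismatch)",
            path,
        )
    return SliceSet(tuple(slices), fingerprint=fingerprint, seed=seed, resolution=resolution)
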