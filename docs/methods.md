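# Methods

## Model and assumptions

The discovery pipeline treats the gene network as an unweighted, undirected
graph (edge weights, when present in the input, are used only for an optional
confidence filter at read time). Activity is binary: a gene is *active* when
its q-value is at or below the activity threshold. All threshold comparisons
in the package are inclusive (≤); sources on this point are mixed between
"<" and "≤", and a single stated convention was preferred over a mixed one.

Slicing assumes community structure at a coarse scale: Louvain is run at
resolution 0.15, which strongly favours large communities. Because
resolution-parameterised Louvain can in principle emit a disconnected
community, each community is decomposed into connected components before the
">3 nodes" slice rule is applied, which guarantees the slice connectivity
invariant for any input graph.

Influence propagation follows the linear-threshold model with synchronous
iterations: the influence of a node with k neighbours on each neighbour is
1/k, and a node activates at the first iteration where the summed influence
of its already-active neighbours *strictly exceeds* θ = 0.5 (a boundary sum
of exactly 0.5 does not activate). Degrees are taken within the slice's
induced subgraph, since propagation runs per slice.

PCST penalties key on *input-active* nodes: an edge is free when incident to
a seed, and costs 1 − ε otherwise. The alternative reading (free when
incident to any propagation-activated node) was rejected because the rest of
the pipeline consistently uses "active" for the input set.

The Girvan–Newman stopping rule compares the modularity of the current
connected-component partition — evaluated on the original sub-slice graph,
the standard practice for edge-removal partitioning — with
log(|sub-slice|)/log(|network|). A sub-slice as large as the network can
never meet the bound (modularity ≤ 1); the loop then degrades to singleton
components, which the final over-representation gate discards.

The mid-pipeline over-representation check that exempts a large sub-slice
from repartitioning uses the raw hypergeometric p ≤ 0.05 (a lenient gate);
the strict Bonferroni-corrected gate (family size = number of putative
modules in the current solution) is applied only at the final step.

## Parameters

| parameter | default | meaning |
|---|---|---|
| activity threshold | 0.05 | q-value cutoff defining active genes |
| Louvain resolution r | 0.15 | coarseness of the one-time slicing |
| min slice size | 4 | "more than three nodes" |
| relevance q | 0.3 | lenient BH-FDR cutoff for relevant slices |
| θ | 0.5 | linear-threshold activation level |
| ε | 1e-4 | penalised edges cost 1 − ε (dimensionless) |
| NG size trigger | 10 | sub-slices larger than this may be repartitioned |
| final q | 0.05 | Bonferroni cutoff for final modules |
| EMP permutations | 5000 | full protocol; 100 and 1000 are desk-scale presets |
| HG / empirical cutoffs | 0.05 / 0.05 | EV-term definition |
| Resnik cutoffs | 1.0–4.0 | redundancy-reduction and homogeneity sweeps |
| subsample fractions | 0.6–0.9 | robustness protocol, 100 iterations each |

## Numerical and algorithmic choices

**PCST.** Instances with ≤ 13 nodes are solved exactly by bitmask
enumeration of connected node subsets (the optimal tree on a fixed node set
is an MST of its induced subgraph). Larger instances use strong pruning of a
minimum-penalty spanning tree, rooted at every prized node (capped at the
200 best prizes above 800 nodes). Strong pruning is exact on trees, and
Kruskal picks all zero-penalty edges first, so the heuristic is exact
whenever an optimum lives inside the MST — the typical situation here, where
free edges cluster around the active genes. Ties everywhere break toward the
lexicographically smallest structure so results are reproducible.

**Empirical significance.** e(t) counts ties as extreme (≥ s), the
conservative reading of 1 − F_t(s); the positively-biased estimator
(1 + count)/(n + 1) is available as an option. Per-permutation RNGs are
derived from (master seed, permutation index), so nulls are identical for
any worker count. Permutation reassigns scores over *all* scored genes,
including genes absent from the network, so the number of on-network active
genes varies across permutations — deliberate, as it mirrors permuting the
dataset rather than the network.

**GO statistics.** Enrichment uses the hypergeometric tail with the network
as background; BH correction runs across terms within each module (the
per-module vs per-solution choice is not externally fixed; per-module is the
default and the machinery accepts any record set). The 5–500 term-size
filter is applied on the full annotation corpus (post-exclusion,
post-propagation), keeping term usability dataset-independent. Terms with
zero module overlap are retained with p = 1 so every usable term has a
well-defined permutation null. Information content uses natural log of the
corpus annotation frequency.

**Redundancy reduction.** The REVIGO-style procedure is a documented
stand-in, not a port: greedily take the most similar pair above the cutoff,
drop the member with the worse enrichment p (ties: drop the lower-IC, i.e.
more general, term). Its post-condition — no surviving pair above the cutoff
— and the monotonicity of richness in the cutoff are property-tested.

**Robustness.** The predicted set for each subsampled run is its HG terms,
not EMP-validated terms: running thousands of permutations inside each of
400 subsample iterations is computationally implausible, and the full-run EV
terms alone serve as the positive set. AUPR uses step-wise summation with
right-interpolated precision (P(r) = max precision at recall ≥ r), which
keeps AUPR within [prevalence, 1] for any ranking; plain average precision
does not satisfy that lower bound under adversarial rankings.

## The synthetic worlds

The default planted world: 500 nodes in 25 stochastic-block-model
communities of 20 (p_in = 0.3, p_out = 0.002, average degree ≈ 6.5 — sparse,
like curated PPI networks); one planted community where 80% of genes draw
q ~ U(0, 0.01); all other genes draw q ~ U(0, 1), giving a ~5% background
active rate at threshold 0.05; a toy BP DAG (root → per-community branch →
leaf) whose per-community leaf terms annotate 90% of the community plus two
random genes, with ten random background terms of 8–40 genes. q-values are
stated directly (p = q) rather than re-derived, since the fixtures model
already-calibrated score tables. The null world is identical but with no
planted community.

What the generator does *not* emulate: scale-free degree structure, hubs
shared between processes, correlated activity among neighbours off the
planted set, ontology depth beyond three levels, and annotation noise beyond
the two random genes per aligned term. Green tests on these worlds establish
that the machinery is implemented as specified and behaves sensibly on
well-separated signal — not that field performance figures on real networks
and datasets are reproduced; those require external data and cluster-scale
permutation runs.

## Known limitations

- PCST above 13 nodes is heuristic; quality degrades if an optimal subtree
  requires many penalised edges outside the MST.
- Girvan–Newman recomputes betweenness after every removal (O(|E|²·|V|)
  worst case); very large sub-slices are slow. In practice the PCST step
  keeps sub-slices small.
- No identifier-namespace mapping: network, score table and GAF must agree;
  the only aid is a logged overlap statistic.
- EHR is undefined (reported as missing) when a solution has no HG terms;
  downstream aggregation across datasets is the caller's concern.
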