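"""EMpirical Pipeline (EMP): per-GO-term permutation nulls and EV terms.

Module discovery plus GO enrichment is rerun on many random permutations of
the gene activity scores; each permutation contributes, per GO term, the
maximal enrichment score -log10(p) over that run's modules (0 when no module
reports the term, including empty solutions).  A term's empirical
significance e(t) is the fraction of null scores at least as large as its
real score.  Terms that pass the hypergeometric test on the real data
(q <= 0.05) AND have e(t) <= 0.05 are the empirically validated (EV) terms;
EHR is the fraction of HG terms that are EV.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from .engine import DominoParams, run_domino
from .go_enrichment import OntologyIndex, module_enrichment, solution_term_scores
from .model_io import ActivityProfile, GeneNetwork, _open_text
from .slicer import SliceSet

log = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "EmpiricalResult",
    "permute_profile",
    "run_and_enrich",
    "build_null",
    "empirical_significance",
    "ev_terms",
    "HG_Q_THRESHOLD",
    "EMPIRICAL_THRESHOLD",
]

HG_Q_THRESHOLD = 0.05
EMPIRICAL_THRESHOLD = 0.05


@dataclass
class NullDistribution:
    """Per-term sorted max-enrichment-score null of length n_permutations."""

    scores: dict              # term -> sorted np.ndarray, len == n_permutations
    n_permutations: int
    seed: int = 0

    def for_term(self, term) -> np.ndarray:
        arr = self.scores.get(term)
        if arr is None:
            return np.zeros(self.n_permutations)
        return arr

    def write(self, out_dir) -> None:
        """Sparse TSV (term, nonzero permutation scores) plus a manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "null_scores.tsv", "w", encoding="utf-8") as fh:
            fh.write("term\tscores\n")
            for term in sorted(self.scores):
                nz = self.scores[term][self.scores[term] > 0]
                fh.write(term + "\t" + ",".join(f"{x:.6g}" for x in nz) + "\n")
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"n_permutations": self.n_permutations, "seed": self.seed},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def read(cls, out_dir) -> "NullDistribution":
        out_dir = Path(out_dir)
        with open(out_dir / "manifest.json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        n = manifest["n_permutations"]
        scores = {}
        with _open_text(out_dir / "null_scores.tsv") as fh:
            next(fh)  # header
            for line in fh:
                term, _, rest = line.rstrip("\n").partition("\t")
                nz = np.array([float(x) for x in rest.split(",") if x], dtype=float)
                full = np.zeros(n)
                if nz.size:
                    full[-nz.size:] = np.sort(nz)
                scores[term] = full
        return cls(scores, n, manifest.get("seed", 0))


@dataclass(frozen=True)
class EmpiricalResult:
    term: str
    score: float          # real enrichment score -log10(p)
    hg_q: float           # best BH q on the real data
    empirical: float      # e(t)
    is_hg: bool
    is_ev: bool


def permute_profile(profile: ActivityProfile, rng: np.random.Generator) -> ActivityProfile:
    """Reassign the (p, q) score records to gene ids by a uniform random
    permutation over ALL scored genes (also those absent from the network);
    the multiset of score pairs is preserved."""
    table = profile.table
    perm = rng.permutation(len(table))
    permuted = table.iloc[perm].copy()
    permuted.index = table.index
    return ActivityProfile(permuted, profile.activity_threshold)


def run_and_enrich(
    network: GeneNetwork,
    slices: SliceSet,
    profile: ActivityProfile,
    index: OntologyIndex,
    params: DominoParams | None = None,
):
    """One full pass: module discovery, per-module GO enrichment, and the
    per-term best scores.  Returns (report, per_module_records, term_scores)."""
    report = run_domino(network, slices, profile, params)
    background = network.nodes
    per_module = [
        module_enrichment(m.nodes, index, background, module_id=i)
        for i, m in enumerate(report.modules)
    ]
    return report, per_module, solution_term_scores(per_module)


def _perm_seed(master_seed: int, idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(idx,)))


def _one_permutation(network, slices, profile, index, params, master_seed, idx):
    rng = _perm_seed(master_seed, idx)
    permuted = permute_profile(profile, rng)
    _report, _records, term_scores = run_and_enrich(
        network, slices, permuted, index, params
    )
    return {t: s for t, (s, _q, _p) in term_scores.items() if s > 0}


def build_null(
    network: GeneNetwork,
    slices: SliceSet,
    profile: ActivityProfile,
    index: OntologyIndex,
    params: DominoParams | None = None,
    n_permutations: int = 5000,
    seed: int = 0,
    n_jobs: int = 1,
) -> NullDistribution:
    """Build the per-term null of max enrichment scores over *n_permutations*
    score permutations.

    Each permutation uses an RNG derived from (seed, permutation index), so
    the null is identical for any worker count.  Terms a permutation does not
    report contribute 0.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    run = delayed(_one_permutation)
    if n_jobs == 1:
        results = [
            _one_permutation(network, slices, profile, index, params, seed, i)
            for i in range(n_permutations)
        ]
    else:
        results = Parallel(n_jobs=n_jobs)(
            run(network, slices, profile, index, params, seed, i)
            for i in range(n_permutations)
        )
    scores = {t: np.zeros(n_permutations) for t in index.usable_terms}
    for i, sparse in enumerate(results):
        for t, s in sparse.items():
            scores[t][i] = s
    for t in scores:
        scores[t].sort()
    return NullDistribution(scores, n_permutations, seed=seed)


def empirical_significance(s: float, null_sorted: np.ndarray, plus_one: bool = False) -> float:
    """e(t) = fraction of null scores >= s (ties count as extreme).

    With ``plus_one``, the positively-biased estimator (1 + count)/(n + 1) is
    used instead.
    """
    null_sorted = np.asarray(null_sorted)
    n = null_sorted.size
    if n == 0:
        raise ValueError("empty null distribution")
    count = n - int(np.searchsorted(null_sorted, s, side="left"))
    if plus_one:
        return (1 + count) / (n + 1)
    return count / n


def ev_terms(
    real_term_scores: dict,
    null: NullDistribution,
    hg_q_threshold: float = HG_Q_THRESHOLD,
    empirical_threshold: float = EMPIRICAL_THRESHOLD,
    plus_one: bool = False,
):
    """Empirical validation of the real solution's terms.

    Returns ``(results, ehr)``: a sorted list of :class:`EmpiricalResult`
    covering every term that appears in the real scores or the null, and the
    EHR (|EV| / |HG|), ``None`` when there are no HG terms.
    """
    terms = sorted(set(real_term_scores) | set(null.scores))
    results = []
    n_hg = n_ev = 0
    for t in terms:
        s, q, _p = real_term_scores.get(t, (0.0, 1.0, 1.0))
        e = empirical_significance(s, null.for_term(t), plus_one=plus_one)
        is_hg = q <= hg_q_threshold
        is_ev = is_hg and e <= empirical_threshold
        n_hg += is_hg
        n_ev += is_ev
        results.append(EmpiricalResult(t, s, q, e, is_hg, is_ev))
    ehr = (n_ev / n_hg) if n_hg else None
    return results, ehr
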