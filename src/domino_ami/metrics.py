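"""Solution-evaluation criteria: mEHR, biological richness, intra-module
homogeneity, and robustness to subsampling (EHR itself lives in ``emp``).

All semantic-similarity work uses Resnik similarity: the information content
(in nats) of the most informative common ancestor of two terms.  Redundancy
reduction and the homogeneity GO graph are swept over similarity cutoffs
1.0–4.0, matching the scale of IC values on typical GO corpora.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .emp import HG_Q_THRESHOLD, run_and_enrich
from .engine import DominoParams
from .go_enrichment import OntologyIndex
from .model_io import ActivityProfile, GeneNetwork
from .slicer import SliceSet

log = logging.getLogger(__name__)

__all__ = [
    "module_ehr",
    "top_k_mean_mehr",
    "resnik_similarity",
    "similarity_matrix",
    "reduce_redundant",
    "intra_module_homogeneity",
    "aupr_from_ranking",
    "robustness",
    "RobustnessReport",
    "DEFAULT_CUTOFFS",
    "DEFAULT_FRACTIONS",
]

DEFAULT_CUTOFFS = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
DEFAULT_FRACTIONS = (0.6, 0.7, 0.8, 0.9)


# ---------------------------------------------------------------------------
# mEHR


def module_ehr(per_module_records, ev_term_set, hg_q_threshold: float = HG_Q_THRESHOLD):
    """Per-module EHR: |module EV terms| / |module HG terms|.

    A module's HG terms are those with BH q <= threshold in its own
    enrichment records; its EV terms are the HG terms that are also in the
    solution-level EV set.  Modules with no HG terms get ``None`` (excluded
    from ranking).
    """
    ev_term_set = frozenset(ev_term_set)
    out = []
    for records in per_module_records:
        hg = {r.term for r in records if r.q_value <= hg_q_threshold}
        if not hg:
            out.append(None)
        else:
            out.append(len(hg & ev_term_set) / len(hg))
    return out


def top_k_mean_mehr(mehr_values, k_max: int = 20) -> dict:
    """Mean mEHR of the top-min(k, n) modules ranked by mEHR, for k = 1..k_max."""
    ranked = sorted((v for v in mehr_values if v is not None), reverse=True)
    if not ranked:
        return {k: None for k in range(1, k_max + 1)}
    return {
        k: float(np.mean(ranked[: min(k, len(ranked))])) for k in range(1, k_max + 1)
    }


# ---------------------------------------------------------------------------
# Resnik similarity and redundancy reduction


def resnik_similarity(t1, t2, index: OntologyIndex) -> float:
    """IC of the most informative common ancestor of t1 and t2 (0 when the
    terms share no ancestor)."""
    common = index.ancestors(t1) & index.ancestors(t2)
    if not common:
        return 0.0
    return max(index.ic(a) for a in common)


def similarity_matrix(terms, index: OntologyIndex) -> dict:
    """Symmetric {frozenset({t1,t2}): sim} over unordered term pairs
    (diagonal included as sim(t,t) = IC(t))."""
    terms = sorted(terms)
    sim = {}
    for i, a in enumerate(terms):
        sim[frozenset((a,))] = index.ic(a)
        for b in terms[i + 1:]:
            sim[frozenset((a, b))] = resnik_similarity(a, b, index)
    return sim


def _pair_sim(sim, a, b) -> float:
    return sim.get(frozenset((a, b)) if a != b else frozenset((a,)), 0.0)


def reduce_redundant(terms, pvals: dict, sim: dict, cutoff: float, index: OntologyIndex):
    """Greedy REVIGO-style redundancy reduction.

    While any pair of surviving terms has similarity > cutoff, take the most
    similar pair and drop the member with the larger (worse) enrichment p;
    on a p tie drop the lower-IC (more general) term.  The survivors are the
    non-redundant set; the biological richness score is their count.
    """
    alive = sorted(terms)
    while len(alive) > 1:
        best_pair, best_sim = None, cutoff
        for i, a in enumerate(alive):
            for b in alive[i + 1:]:
                s = _pair_sim(sim, a, b)
                if s > best_sim or (best_pair and s == best_sim and (a, b) < best_pair):
                    best_pair, best_sim = (a, b), s
        if best_pair is None:
            break
        a, b = best_pair
        pa, pb = pvals.get(a, 1.0), pvals.get(b, 1.0)
        if pa > pb:
            drop = a
        elif pb > pa:
            drop = b
        else:
            drop = a if index.ic(a) <= index.ic(b) else b
        alive.remove(drop)
    return alive


# ---------------------------------------------------------------------------
# Intra-module homogeneity


def _density(terms, sim, cutoff) -> tuple:
    """(surviving edges, complete-graph edges) of the thresholded GO graph."""
    terms = sorted(terms)
    n = len(terms)
    total = n * (n - 1) // 2
    kept = 0
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            if _pair_sim(sim, a, b) >= cutoff:
                kept += 1
    return kept, total


def intra_module_homogeneity(module_ev_terms, solution_ev_terms, sim, cutoff: float):
    """Module scores and solution mean of relative edge density in the
    cutoff-thresholded Resnik GO graph.

    Each module's score is (module surviving-edge density) / (solution
    surviving-edge density).  Modules with < 2 EV terms score 0; if the
    solution has < 2 EV terms or no surviving edges, all scores are 0.
    """
    solution_ev_terms = sorted(set(solution_ev_terms))
    kept_sol, total_sol = _density(solution_ev_terms, sim, cutoff)
    if total_sol == 0 or kept_sol == 0:
        return [0.0] * len(module_ev_terms), 0.0
    sol_density = kept_sol / total_sol
    scores = []
    for terms in module_ev_terms:
        terms = sorted(set(terms) & set(solution_ev_terms))
        kept, total = _density(terms, sim, cutoff)
        scores.append(0.0 if total == 0 else (kept / total) / sol_density)
    mean = float(np.mean(scores)) if scores else 0.0
    return scores, mean


# ---------------------------------------------------------------------------
# Robustness


def aupr_from_ranking(ranked_terms, positives) -> float:
    """Step-wise (trapezoid-free) area under the precision-recall curve for a
    ranking, with right-interpolated precision: AUPR = sum over ranks of
    (R_k - R_{k-1}) * max_{j >= k} P_j.  Bounded below by the prevalence."""
    positives = frozenset(positives)
    if not positives:
        raise ValueError("no positive terms; AUPR undefined")
    tp = 0
    precisions, recalls = [], []
    for i, t in enumerate(ranked_terms, start=1):
        if t in positives:
            tp += 1
        precisions.append(tp / i)
        recalls.append(tp / len(positives))
    # right-interpolate precision
    for i in range(len(precisions) - 2, -1, -1):
        precisions[i] = max(precisions[i], precisions[i + 1])
    area, prev_r = 0.0, 0.0
    for p, r in zip(precisions, recalls):
        area += (r - prev_r) * p
        prev_r = r
    return area


@dataclass
class RobustnessReport:
    """Per-subsampling-fraction precision/recall/F1 (mean over iterations),
    frequency-ranked AUPR, and the non-empty-solution fraction."""

    per_fraction: dict = field(default_factory=dict)
    undefined: bool = False

    def to_dict(self) -> dict:
        return {"undefined": self.undefined,
                "per_fraction": {f"{f:g}": v for f, v in self.per_fraction.items()}}


def _subsample_profile(profile: ActivityProfile, fraction: float,
                       rng: np.random.Generator) -> ActivityProfile:
    """Retain a uniform random fraction of scored genes (others missing)."""
    genes = np.array(sorted(profile.table.index))
    keep_n = max(1, int(round(fraction * len(genes))))
    keep = rng.choice(genes, size=keep_n, replace=False)
    return ActivityProfile(profile.table.loc[sorted(keep)].copy(),
                           profile.activity_threshold)


def robustness(
    network: GeneNetwork,
    slices: SliceSet,
    profile: ActivityProfile,
    index: OntologyIndex,
    full_ev_terms,
    fractions=DEFAULT_FRACTIONS,
    n_iter: int = 100,
    seed: int = 0,
    params: DominoParams | None = None,
    hg_q_threshold: float = HG_Q_THRESHOLD,
) -> RobustnessReport:
    """Stability of the solution's EV terms under activity-data subsampling.

    For each fraction and iteration, a random subset of scored genes is kept
    and the discovery + enrichment pass rerun; the predicted set is that
    run's HG terms (q <= threshold).  Precision/recall/F1 are averaged over
    iterations against the full-run EV terms; AUPR ranks terms by detection
    frequency across the iterations with the EV terms as positives.
    """
    positives = frozenset(full_ev_terms)
    report = RobustnessReport()
    if not positives:
        report.undefined = True
        return report
    for f_i, fraction in enumerate(fractions):
        precs, recs, f1s = [], [], []
        freq = {}
        non_empty = 0
        for it in range(n_iter):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(f_i, it))
            )
            sub_profile = _subsample_profile(profile, fraction, rng)
            _rep, per_module, term_scores = run_and_enrich(
                network, slices, sub_profile, index, params
            )
            predicted = {t for t, (_s, q, _p) in term_scores.items()
                         if q <= hg_q_threshold}
            non_empty += bool(predicted)
            for t in predicted:
                freq[t] = freq.get(t, 0) + 1
            tp = len(predicted & positives)
            prec = tp / len(predicted) if predicted else 0.0
            rec = tp / len(positives)
            f1 = (2 * prec * rec / (prec + rec)) if (prec + rec) else 0.0
            precs.append(prec)
            recs.append(rec)
            f1s.append(f1)
        universe = sorted(set(freq) | positives)
        ranked = sorted(universe, key=lambda t: (-freq.get(t, 0), t))
        report.per_fraction[fraction] = {
            "precision": float(np.mean(precs)),
            "recall": float(np.mean(recs)),
            "f1": float(np.mean(f1s)),
            "aupr": aupr_from_ranking(ranked, positives),
            "non_empty_fraction": non_empty / n_iter,
        }
    return report
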