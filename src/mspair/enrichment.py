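"""Metabolite-set enrichment and overrepresentation statistics.

Significance is layered: a nominal two-tailed rank-sum p per set (absolute
annotation scores of trait-positive vs negative signals), a permutation p
adjusting for set-specific bias (observed nominal p compared against the
nominal p's of permuted trait rankings), and an analysis-wide FDR from a
second, smaller batch of null lists whose permutation p's are computed
against the same first-round nulls, monotonized so a smaller permutation p
never has a larger FDR.  Overrepresentation analysis mirrors the same
permutation layers with a one-sided Fisher (hypergeometric) test on binary
annotations in place of the rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import ranksum_z_matrix
from .datatypes import MetaboliteSet, ValidationError
from .pathways import AnnotationMatrix, _membership_matrix

logger = logging.getLogger("mspair")

__all__ = [
    "EnrichmentResult",
    "ranksum_enrichment",
    "permutation_pvalues",
    "estimate_fdr",
    "run_enrichment",
    "overrepresentation",
    "overlap_significance",
]


@dataclass
class EnrichmentResult:
    """Per-set enrichment statistics (one row of the output table)."""

    set_id: str
    nominal_p: float
    perm_p: float
    fdr: float
    n_positive: int
    pathway_labels: tuple[str, ...]


def _positive_mask(matrix: AnnotationMatrix, positives, negatives) -> tuple[np.ndarray, list[str]]:
    pos = list(positives)
    neg = list(negatives)
    if not pos or not neg:
        raise ValidationError("positive and negative lists must be non-empty")
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValidationError(f"signals in both lists: {sorted(overlap)[:5]}")
    all_ids = pos + neg
    missing = set(all_ids) - set(matrix.scores.index)
    if missing:
        raise ValidationError(f"signals absent from matrix: {sorted(missing)[:5]}")
    mask = np.zeros(len(all_ids), dtype=bool)
    mask[: len(pos)] = True
    return mask, all_ids


def ranksum_enrichment(matrix: AnnotationMatrix, positives, negatives) -> pd.Series:
    """Nominal enrichment p per set: two-tailed rank-sum on absolute scores
    of the positive vs negative signals."""
    mask, ids = _positive_mask(matrix, positives, negatives)
    A = np.abs(matrix.scores.loc[ids].to_numpy())
    _, P = ranksum_z_matrix(A, mask[:, None])
    return pd.Series(P[:, 0], index=matrix.scores.columns, name="nominal_p")


class _RanksumEngine:
    """Cached rank transform for repeated positive-list evaluations over the
    same signal universe (the permutation layers)."""

    def __init__(self, matrix: AnnotationMatrix, signal_ids):
        self.ids = list(signal_ids)
        A = np.abs(matrix.scores.loc[self.ids].to_numpy())
        self.values = A
        self.n, self.m = A.shape
        self.ranks = stats.rankdata(A, axis=0)
        tie = np.zeros(self.m)
        for j in range(self.m):
            _, counts = np.unique(A[:, j], return_counts=True)
            t = counts[counts > 1].astype(float)
            tie[j] = np.sum(t**3 - t)
        self.tie = tie
        self.index = {s: i for i, s in enumerate(self.ids)}

    def pvalues(self, positive_rows: np.ndarray) -> np.ndarray:
        """Nominal p per set for a positive list given as row indices."""
        from ._stats import EXACT_RANKSUM_N

        if self.n <= EXACT_RANKSUM_N:
            neg = np.setdiff1d(np.arange(self.n), positive_rows)
            return np.array(
                [
                    stats.mannwhitneyu(
                        self.values[positive_rows, j], self.values[neg, j],
                        alternative="two-sided",
                    ).pvalue
                    for j in range(self.m)
                ]
            )
        n1 = float(len(positive_rows))
        w = self.ranks[positive_rows].sum(axis=0)
        mu = n1 * (self.n + 1) / 2.0
        var = (n1 * (self.n - n1) / 12.0) * ((self.n + 1) - self.tie / (self.n * (self.n - 1.0)))
        var = np.maximum(var, 0)
        diff = w - mu
        corr = np.where(diff > 0, -0.5, np.where(diff < 0, 0.5, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var > 0, (diff + corr) / np.sqrt(var), 0.0)
        return np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)


def _null_positive_rows(engine: _RanksumEngine, trait_scores: pd.Series, n_positive: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Top-N rows after shuffling the per-signal trait statistic.

    Higher trait score = stronger association; shuffling the scores over
    signals and re-ranking yields the null positive list.
    """
    shuffled = rng.permutation(trait_scores.to_numpy(dtype=float))
    order = np.argsort(-shuffled, kind="stable")
    return order[:n_positive]


def permutation_pvalues(
    matrix: AnnotationMatrix,
    trait_scores: pd.Series,
    n_positive: int,
    n_perm: int = 1000,
    seed: int = 0,
    plus_one: bool = False,
    _engine: _RanksumEngine | None = None,
    _return_null: bool = False,
):
    """Permutation p per set for the observed positive list (top-N signals
    by trait score).

    Each permutation shuffles the trait statistic over signals, takes the
    top-N as the null positive list and recomputes the nominal rank-sum p;
    perm_p = (# null p <= observed p) / n_perm (inclusive ties;
    ``plus_one`` switches to the conservative (k+1)/(n+1) variant).
    """
    ids = list(trait_scores.index)
    if n_positive < 1 or n_positive >= len(ids):
        raise ValidationError("n_positive must be in [1, n_signals)")
    engine = _engine or _RanksumEngine(matrix, ids)
    rng = np.random.default_rng(seed)
    order = np.argsort(-trait_scores.to_numpy(dtype=float), kind="stable")
    obs_rows = order[:n_positive]
    obs_p = engine.pvalues(obs_rows)
    null_p = np.empty((n_perm, engine.m))
    for b in range(n_perm):
        null_p[b] = engine.pvalues(_null_positive_rows(engine, trait_scores, n_positive, rng))
    k = (null_p <= obs_p[None, :]).sum(axis=0)
    perm = (k + 1) / (n_perm + 1) if plus_one else k / n_perm
    perm = pd.Series(perm, index=matrix.scores.columns, name="perm_p")
    if _return_null:
        return perm, obs_p, null_p
    return perm


def estimate_fdr(
    observed_perm_p: pd.Series,
    null_rank_p: np.ndarray,
    matrix: AnnotationMatrix,
    trait_scores: pd.Series,
    n_positive: int,
    n_null_lists: int = 20,
    seed: int = 1,
    plus_one: bool = False,
    _engine: _RanksumEngine | None = None,
) -> pd.Series:
    """Analysis-wide FDR for the observed permutation p-values.

    ``n_null_lists`` extra null lists are scored against the same first-round
    null rank-sum p sets, giving null permutation p's.  FDR at each observed
    perm p threshold P = (average # null perm p <= P per list) / (# observed
    perm p <= P), clamped to [0, 1] and monotonized by a running maximum from
    the smallest P upward (conservative: estimates are only ever raised, so a
    smaller perm p never carries a larger FDR).
    """
    engine = _engine or _RanksumEngine(matrix, list(trait_scores.index))
    rng = np.random.default_rng(seed)
    n_perm = null_rank_p.shape[0]
    null_perm = np.empty((n_null_lists, engine.m))
    for b in range(n_null_lists):
        p_b = engine.pvalues(_null_positive_rows(engine, trait_scores, n_positive, rng))
        k = (null_rank_p <= p_b[None, :]).sum(axis=0)
        null_perm[b] = (k + 1) / (n_perm + 1) if plus_one else k / n_perm
    obs = observed_perm_p.to_numpy()
    fdr = np.empty_like(obs)
    for j, P in enumerate(obs):
        n_obs = (obs <= P).sum()
        avg_null = (null_perm <= P).sum() / n_null_lists
        fdr[j] = 0.0 if n_obs == 0 else min(avg_null / n_obs, 1.0)
    # monotonize: scan from smallest perm p up, taking the running maximum
    order = np.argsort(obs, kind="stable")
    running = np.maximum.accumulate(fdr[order])
    out = np.empty_like(fdr)
    out[order] = running
    return pd.Series(out, index=observed_perm_p.index, name="fdr")


def run_enrichment(
    matrix: AnnotationMatrix,
    trait_scores: pd.Series,
    n_positive: int,
    n_perm: int = 1000,
    n_null_lists: int = 20,
    seed: int = 0,
    plus_one: bool = False,
) -> pd.DataFrame:
    """Full enrichment pipeline: nominal p, permutation p, FDR per set."""
    engine = _RanksumEngine(matrix, list(trait_scores.index))
    perm_p, obs_p, null_p = permutation_pvalues(
        matrix, trait_scores, n_positive, n_perm=n_perm, seed=seed,
        plus_one=plus_one, _engine=engine, _return_null=True,
    )
    fdr = estimate_fdr(
        perm_p, null_p, matrix, trait_scores, n_positive,
        n_null_lists=n_null_lists, seed=seed + 1, plus_one=plus_one, _engine=engine,
    )
    labels = {s.set_id: "|".join(s.pathway_labels) for s in matrix.sets}
    out = pd.DataFrame(
        {
            "SET_ID": matrix.scores.columns,
            "Nominal_P": obs_p,
            "Perm_P": perm_p.to_numpy(),
            "FDR": fdr.to_numpy(),
            "N_Positive": n_positive,
            "CPDB_Pathways": [labels.get(s, "") for s in matrix.scores.columns],
        }
    )
    if matrix.label_p is not None:
        out["Label_P"] = matrix.label_p.reindex(out["SET_ID"]).to_numpy()
    return out


# ---------------------------------------------------------------------------
# overrepresentation (binary annotations)


def overlap_significance(nA: int, nB: int, nBoth: int, nTotal: int) -> float:
    """One-sided hypergeometric upper-tail p of observing >= nBoth overlaps
    between a set of size nA and a set of size nB drawn from nTotal items."""
    if nBoth > min(nA, nB) or nA + nB - nBoth > nTotal or min(nA, nB, nBoth, nTotal) < 0:
        raise ValidationError("inconsistent overlap counts")
    return float(stats.hypergeom.sf(nBoth - 1, nTotal, nA, nB))


def overrepresentation(
    known_sets: list[MetaboliteSet],
    trait_positive_knowns,
    all_knowns,
    n_perm: int = 1000,
    n_null_lists: int = 20,
    seed: int = 0,
    plus_one: bool = False,
) -> pd.DataFrame:
    """Fisher overrepresentation of trait-associated known metabolites in
    binary metabolite sets, with the same permutation-p / FDR layers as the
    rank-sum enrichment (null positive lists are shuffled draws of the same
    size from ``all_knowns``)."""
    pos = list(dict.fromkeys(trait_positive_knowns))
    universe = list(dict.fromkeys(all_knowns))
    if not pos:
        raise ValidationError("empty positive metabolite list")
    if not set(pos) <= set(universe):
        raise ValidationError("positives must be a subset of all_knowns")
    M = _membership_matrix(known_sets, universe)  # (n_known, n_sets)
    n_total = len(universe)
    n_pos = len(pos)
    set_sizes = M.sum(axis=0)
    idx = {m: i for i, m in enumerate(universe)}
    pos_rows = np.array([idx[m] for m in pos])

    def fisher_ps(rows) -> np.ndarray:
        overlap = M[rows].sum(axis=0)
        return stats.hypergeom.sf(overlap - 1, n_total, set_sizes, len(rows))

    obs_p = fisher_ps(pos_rows)
    rng = np.random.default_rng(seed)
    null_p = np.empty((n_perm, len(known_sets)))
    for b in range(n_perm):
        null_p[b] = fisher_ps(rng.choice(n_total, size=n_pos, replace=False))
    k = (null_p <= obs_p[None, :]).sum(axis=0)
    perm = (k + 1) / (n_perm + 1) if plus_one else k / n_perm
    null_perm = np.empty((n_null_lists, len(known_sets)))
    for b in range(n_null_lists):
        pb = fisher_ps(rng.choice(n_total, size=n_pos, replace=False))
        kb = (null_p <= pb[None, :]).sum(axis=0)
        null_perm[b] = (kb + 1) / (n_perm + 1) if plus_one else kb / n_perm
    fdr = np.empty_like(perm)
    for j, P in enumerate(perm):
        n_obs = (perm <= P).sum()
        avg_null = (null_perm <= P).sum() / n_null_lists
        fdr[j] = 0.0 if n_obs == 0 else min(avg_null / n_obs, 1.0)
    order = np.argsort(perm, kind="stable")
    running = np.maximum.accumulate(fdr[order])
    mono = np.empty_like(fdr)
    mono[order] = running
    return pd.DataFrame(
        {
            "SET_ID": [s.set_id for s in known_sets],
            "Fisher_P": obs_p,
            "Perm_P": perm,
            "FDR": mono,
            "CPDB_Pathways": ["|".join(s.pathway_labels) for s in known_sets],
        }
    )
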