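"""Genetic validation of matched signals and pathway annotations.

Matched signal pairs are validated through directional consistency: for each
pair, the variant with the best direction-ignoring inverse-variance meta p
is selected, and the pair counts as consistent when the original effect
signs agree across the two cohorts.  Shared known metabolites provide the
consistency ceiling *s*, random re-pairings the chance floor (~0.5), and the
true-positive fraction interpolates between them.  Pathway annotations are
validated at the locus level: signals associated with a coding variant
should be enriched for pathways curated to the affected gene more often
than under permuted association inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AssocStats, ValidationError
from .enrichment import ranksum_enrichment
from .pathways import AnnotationMatrix

logger = logging.getLogger("mspair")

__all__ = [
    "ivw_meta",
    "best_variant_per_pair",
    "ConsistencySummary",
    "consistency_curve",
    "consistency_significance",
    "empirical_consistency_p",
    "true_positive_fraction",
    "LocusValidation",
    "locus_pathway_validation",
]


def ivw_meta(beta1, se1, beta2, se2, force_positive: bool = False):
    """Fixed-effect inverse-variance-weighted meta-analysis of two studies.

    w_i = 1/se_i^2; beta = sum(w b)/sum(w); se = 1/sqrt(sum w); two-sided
    normal p.  ``force_positive`` replaces each beta by its absolute value
    before combining (direction-ignoring meta used for best-variant
    selection).  Accepts scalars or arrays.
    """
    b1 = np.asarray(beta1, dtype=float)
    b2 = np.asarray(beta2, dtype=float)
    s1 = np.asarray(se1, dtype=float)
    s2 = np.asarray(se2, dtype=float)
    if not (np.all(np.isfinite(b1)) and np.all(np.isfinite(b2))
            and np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
        raise ValidationError("non-finite meta-analysis inputs")
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValidationError("standard errors must be positive")
    if force_positive:
        b1, b2 = np.abs(b1), np.abs(b2)
    w1, w2 = 1.0 / s1**2, 1.0 / s2**2
    beta = (w1 * b1 + w2 * b2) / (w1 + w2)
    se = 1.0 / np.sqrt(w1 + w2)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, z, p


def best_variant_per_pair(assoc1: pd.DataFrame, assoc2: pd.DataFrame):
    """Best shared variant for one matched signal pair.

    ``assoc1`` / ``assoc2`` are per-cohort tables (variant_id, beta, se, p)
    for the two signals.  The variant minimizing the force-positive IVW meta
    p is returned as (variant_id, meta_p, sign1, sign2); ties go to the
    lexicographically smaller variant id; None if no shared variants.
    """
    m = assoc1.merge(assoc2, on="variant_id", suffixes=("_1", "_2"))
    if m.empty:
        return None
    _, _, _, p = ivw_meta(m["beta_1"], m["se_1"], m["beta_2"], m["se_2"], force_positive=True)
    m = m.assign(meta_p=p).sort_values(["meta_p", "variant_id"], kind="mergesort")
    top = m.iloc[0]
    return (
        str(top["variant_id"]),
        float(top["meta_p"]),
        int(np.sign(top["beta_1"])),
        int(np.sign(top["beta_2"])),
    )


def pair_best_variants(assoc: AssocStats, pairs: pd.DataFrame,
                       cohort1: str, cohort2: str) -> pd.DataFrame:
    """Best variant + signs for every matched pair in a MatchResult table."""
    a1 = assoc.for_cohort(cohort1)
    a2 = assoc.for_cohort(cohort2)
    g1 = dict(tuple(a1.groupby("signal_id")))
    g2 = dict(tuple(a2.groupby("signal_id")))
    rows = []
    for s1, s2 in zip(pairs["signal1_id"], pairs["signal2_id"]):
        t1, t2 = g1.get(s1), g2.get(s2)
        if t1 is None or t2 is None:
            continue
        hit = best_variant_per_pair(t1, t2)
        if hit is None:
            continue
        rows.append((s1, s2, *hit))
    return pd.DataFrame(
        rows, columns=["signal1_id", "signal2_id", "variant_id", "meta_p", "sign1", "sign2"]
    )


@dataclass
class ConsistencySummary:
    """Directional-consistency tally at one meta p threshold."""

    p_threshold: float
    n_total: int
    n_consistent: int
    fraction: float
    significance_p: float | None = None
    empirical_p: float | None = None
    shared_known_fraction: float | None = None
    tp_fraction: float | None = None
    tp_count: float | None = None


def consistency_curve(best: pd.DataFrame, p_thresholds) -> list[ConsistencySummary]:
    """Consistency fraction at each meta-p threshold (descending from 5e-8).

    A pair is consistent when its original effect signs agree; a zero beta
    counts as inconsistent (conservative).
    """
    out = []
    consistent = (best["sign1"] == best["sign2"]) & (best["sign1"] != 0)
    for thr in p_thresholds:
        sel = best["meta_p"] < thr
        n = int(sel.sum())
        if n == 0:
            out.append(ConsistencySummary(thr, 0, 0, float("nan")))
            continue
        nc = int((consistent & sel).sum())
        out.append(
            ConsistencySummary(
                thr, n, nc, nc / n, significance_p=consistency_significance(nc, n)
            )
        )
    return out


def consistency_significance(n_consistent: int, n_total: int) -> float | None:
    """Two-sided exact binomial test of the consistency count against 0.5.

    Tail-doubling convention; at p0 = 0.5 the distribution is symmetric so
    this coincides with the minimum-likelihood two-sided p.  Returns None
    when no pairs pass the threshold.
    """
    if n_total == 0:
        return None
    if not 0 <= n_consistent <= n_total:
        raise ValidationError("n_consistent must be in [0, n_total]")
    k = max(n_consistent, n_total - n_consistent)
    return float(min(1.0, 2.0 * stats.binom.sf(k - 1, n_total, 0.5)))


def empirical_consistency_p(
    observed_fraction: float,
    best: pd.DataFrame,
    assoc: AssocStats,
    cohort1: str,
    cohort2: str,
    pairs: pd.DataFrame,
    p_threshold: float = 5e-8,
    n_shuffle: int = 20,
    seed: int = 0,
) -> float:
    """Empirical p for an observed consistency fraction.

    ``n_shuffle`` random re-pairings preserve the multiset of dataset-2
    partners; each shuffle re-runs the full best-variant + consistency
    pipeline; p = proportion of null fractions >= observed.
    """
    rng = np.random.default_rng(seed)
    s2 = pairs["signal2_id"].to_numpy()
    count = 0
    for _ in range(n_shuffle):
        shuffled = pairs.copy()
        shuffled["signal2_id"] = rng.permutation(s2)
        b = pair_best_variants(assoc, shuffled, cohort1, cohort2)
        summ = consistency_curve(b, [p_threshold])[0]
        frac = summ.fraction if summ.n_total > 0 else 0.0
        if frac >= observed_fraction:
            count += 1
    return count / n_shuffle


def true_positive_fraction(c: float, s: float, n_total: int | None = None):
    """Estimated true-positive fraction (c - 0.5)/(s - 0.5) clamped to [0, 1].

    *c* is the consistency fraction of the matched pairs and *s* that of the
    shared knowns; chance consistency is 0.5.  Undefined (None) when
    s <= 0.5.  Returns (fraction, count) where count = fraction * n_total
    when ``n_total`` is given.
    """
    if s <= 0.5:
        return None, None
    frac = min(max((c - 0.5) / (s - 0.5), 0.0), 1.0)
    count = None if n_total is None else frac * n_total
    return frac, count


# ---------------------------------------------------------------------------
# locus-level pathway validation


@dataclass
class LocusValidation:
    variant_id: str
    gene: str
    associated_signal_ids: list[str]
    enriched_gene_pathways: dict[float, list[str]]


def locus_pathway_validation(
    assoc: pd.DataFrame,
    matches: pd.DataFrame,
    annot: AnnotationMatrix,
    gene_pathways: dict[str, set],
    variant_annotations: pd.DataFrame,
    thresholds=(0.01, 0.05),
    assoc_p_max: float = 1e-5,
    min_signals: int = 5,
    n_null: int = 20,
    seed: int = 0,
):
    """Locus-level validation of reconstituted pathway annotations.

    Variants are retained when they (1) are associated with >= ``min_signals``
    study signals at p < ``assoc_p_max``, (2) are coding (missense/nonsense
    per ``variant_annotations``), and (3) affect a gene linked to >= 1
    pathway used in reconstitution; one variant (best p) is kept per gene.
    Study signals are mapped to the annotation reference via ``matches``
    (signal1_id -> signal2_id).  Per locus and per enrichment threshold, the
    SNP-associated reference signals form the positive list of a rank-sum
    enrichment; a locus validates when >= 1 enriched set carries a pathway
    label linked to the gene.  ``n_null`` iterations with random positive
    lists of the same sizes give empirical p = proportion(null count >=
    observed).

    Returns (loci: list[LocusValidation], summary DataFrame with observed
    counts and empirical p per threshold).
    """
    sig_map = dict(zip(matches["signal1_id"], matches["signal2_id"]))
    va = variant_annotations.set_index("variant_id")
    coding = {"missense", "nonsense"}
    cand = assoc[assoc["p"] < assoc_p_max]
    by_variant = cand.groupby("variant_id")
    per_gene: dict[str, tuple[str, float, list[str]]] = {}
    for vid, grp in by_variant:
        mapped = sorted({sig_map[s] for s in grp["signal_id"] if s in sig_map})
        if len(mapped) < min_signals:
            continue
        if vid not in va.index:
            continue
        if str(va.loc[vid, "mutation"]) not in coding:
            continue
        gene = str(va.loc[vid, "gene"])
        if gene not in gene_pathways or not gene_pathways[gene]:
            continue
        best_p = float(grp["p"].min())
        if gene not in per_gene or best_p < per_gene[gene][1]:
            per_gene[gene] = (str(vid), best_p, mapped)
    if not per_gene:
        logger.warning("no loci pass the filters")
        return [], pd.DataFrame(columns=["threshold", "observed", "null_mean", "empirical_p"])

    all_signals = list(annot.scores.index)
    set_labels = {s.set_id: set(s.pathway_labels) for s in annot.sets}

    def count_validated(loci_signals: dict[str, tuple[str, list[str]]]):
        counts = {thr: 0 for thr in thresholds}
        details: dict[str, dict[float, list[str]]] = {}
        for gene, (vid, mapped) in loci_signals.items():
            positives = [s for s in mapped if s in annot.scores.index]
            negatives = [s for s in all_signals if s not in set(positives)]
            if not positives:
                continue
            p = ranksum_enrichment(annot, positives, negatives)
            details[gene] = {}
            for thr in thresholds:
                enriched = set(p.index[p < thr])
                hits = sorted(
                    lbl
                    for sid in enriched
                    for lbl in set_labels[sid] & gene_pathways[gene]
                )
                details[gene][thr] = hits
                if hits:
                    counts[thr] += 1
        return counts, details

    observed_input = {g: (v[0], v[2]) for g, v in per_gene.items()}
    obs_counts, obs_details = count_validated(observed_input)
    rng = np.random.default_rng(seed)
    null_counts = {thr: [] for thr in thresholds}
    for _ in range(n_null):
        null_input = {}
        for gene, (vid, mapped) in observed_input.items():
            pick = rng.choice(len(all_signals), size=len(mapped), replace=False)
            null_input[gene] = (vid, [all_signals[i] for i in pick])
        nc, _ = count_validated(null_input)
        for thr in thresholds:
            null_counts[thr].append(nc[thr])
    rows = []
    for thr in thresholds:
        nulls = np.array(null_counts[thr])
        rows.append(
            {
                "threshold": thr,
                "observed": obs_counts[thr],
                "null_mean": float(nulls.mean()),
                "empirical_p": float((nulls >= obs_counts[thr]).mean()),
            }
        )
    loci = [
        LocusValidation(vid, gene, mapped, obs_details.get(gene, {}))
        for gene, (vid, _, mapped) in per_gene.items()
    ]
    return loci, pd.DataFrame(rows)
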