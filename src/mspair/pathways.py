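"""Metabolic components and metabolite-set reconstitution.

Pathway annotations are binary and cover only identified metabolites.  To
extend them to every profiled signal, the signal-signal Spearman correlation
matrix is eigendecomposed into "metabolic components" (MCs, modules of
covarying signals).  For each curated metabolite set and each MC a signed
rank-sum z compares the MC loadings of in-set vs out-of-set known
metabolites; the Spearman correlation between a signal's loading profile and
a set's z profile across the selected MCs is then that signal's membership
score in the set.  Leave-one-out recomputation prevents a known metabolite's
own data from inflating its score in its own sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._stats import ranksum_z_matrix
from .datatypes import MetaboliteSet, PathwayAnnotation, ProfilingDataset, ValidationError

logger = logging.getLogger("mspair")

__all__ = [
    "consolidate_metabolite_sets",
    "MCModel",
    "compute_mcs",
    "mc_set_enrichment",
    "select_mcs",
    "AnnotationMatrix",
    "reconstitute",
    "annotation_pvalues",
    "classification_auc",
    "label_confidence",
]


def consolidate_metabolite_sets(
    pathways: list[PathwayAnnotation], dataset_knowns, min_size: int = 2
) -> list[MetaboliteSet]:
    """Merge pathways into metabolite sets with unique profiled-member
    combinations.

    Members are first intersected with the known metabolites profiled in the
    dataset; pathways whose post-intersection member sets coincide are merged
    into one set carrying all their labels; sets smaller than ``min_size``
    are dropped.
    """
    knowns = set(dataset_knowns)
    by_members: dict[frozenset, list[str]] = {}
    for pw in pathways:
        members = frozenset(pw.members & knowns)
        if len(members) < min_size:
            continue
        by_members.setdefault(members, []).append(pw.pathway_label)
    sets = []
    ordered = sorted(by_members.items(), key=lambda kv: sorted(kv[1])[0])
    for i, (members, labels) in enumerate(ordered):
        sets.append(
            MetaboliteSet(
                set_id=f"SET_{i:04d}",
                members=members,
                pathway_labels=tuple(sorted(labels)),
                min_size_class=min_size,
            )
        )
    logger.info("consolidated %d pathways into %d metabolite sets", len(pathways), len(sets))
    return sets


@dataclass
class MCModel:
    """Eigendecomposition of the signal Spearman-correlation matrix.

    ``loadings`` is the signals x MCs eigenvector matrix (columns
    orthonormal, ordered by decreasing eigenvalue); ``variance_explained``
    is eigenvalue / trace.
    """

    signal_ids: list[str]
    known_names: pd.Series  # signal_id -> known name, knowns only
    eigenvalues: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    enrichment: pd.DataFrame | None = None  # per-(mc, set) p and fdr

    @property
    def n_mcs(self) -> int:
        return self.loadings.shape[1]

    def known_loadings(self) -> tuple[np.ndarray, list[str]]:
        """Loadings restricted to known-metabolite signals, with names."""
        idx = [self.signal_ids.index(s) for s in self.known_names.index]
        return self.loadings[idx, :], list(self.known_names)


def compute_mcs(ds: ProfilingDataset, scale_by_eigenvalue: bool = False) -> MCModel:
    """Metabolic components of a complete dataset.

    Spearman correlations are computed across samples for all signal pairs;
    the symmetric eigendecomposition supplies the components.  Raw
    eigenvector loadings are returned unless ``scale_by_eigenvalue``, which
    multiplies each column by sqrt(eigenvalue) (clipped at zero).
    """
    X = ds.abundance.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("dataset must be complete (impute first)")
    R = stats.rankdata(X, axis=0)
    C = np.corrcoef(R, rowvar=False)
    if not np.all(np.isfinite(C)):
        raise ValidationError("non-finite correlations (constant signal?)")
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if scale_by_eigenvalue:
        vecs = vecs * np.sqrt(np.clip(vals, 0, None))[None, :]
    return MCModel(
        signal_ids=ds.signal_ids,
        known_names=ds.known_names,
        eigenvalues=vals,
        loadings=vecs,
        variance_explained=vals / np.sum(vals),
    )


def _membership_matrix(sets: list[MetaboliteSet], known_names: list[str]) -> np.ndarray:
    M = np.zeros((len(known_names), len(sets)), dtype=bool)
    name_idx = {n: i for i, n in enumerate(known_names)}
    for j, s in enumerate(sets):
        for m in s.members:
            if m in name_idx:
                M[name_idx[m], j] = True
    return M


def mc_set_enrichment(
    mcm: MCModel, sets: list[MetaboliteSet], n_null: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Rank-sum enrichment of every metabolite set in every MC, with a
    permutation-based FDR.

    The observed two-tailed rank-sum p compares in-set vs out-of-set known
    metabolites' MC loadings.  ``n_null`` iterations permute which known
    carries which loading row; FDR at an observed p-value threshold P is
    (average null count <= P per iteration) / (observed count <= P).
    Pairs where a set contains all knowns or none are skipped.
    """
    K, names = mcm.known_loadings()
    M = _membership_matrix(sets, names)
    n1 = M.sum(axis=0)
    usable = (n1 > 0) & (n1 < len(names))
    if not usable.any():
        raise ValidationError("no usable metabolite sets")
    _, P = ranksum_z_matrix(K, M[:, usable])  # (n_mc, n_usable)
    rng = np.random.default_rng(seed)
    null_ps = []
    for _ in range(n_null):
        perm = rng.permutation(K.shape[0])
        _, Pn = ranksum_z_matrix(K[perm], M[:, usable])
        null_ps.append(Pn.ravel())
    null_flat = np.concatenate(null_ps)
    obs_flat = P.ravel()
    order = np.sort(obs_flat)
    null_sorted = np.sort(null_flat)
    obs_counts = np.searchsorted(order, obs_flat, side="right")
    null_counts = np.searchsorted(null_sorted, obs_flat, side="right") / n_null
    fdr = np.clip(np.where(obs_counts > 0, null_counts / np.maximum(obs_counts, 1), 0.0), 0, 1)
    mc_idx, set_idx = np.meshgrid(
        np.arange(mcm.n_mcs), np.where(usable)[0], indexing="ij"
    )
    return pd.DataFrame(
        {
            "mc": mc_idx.ravel(),
            "set_id": [sets[j].set_id for j in set_idx.ravel()],
            "p": obs_flat,
            "fdr": fdr,
        }
    )


def select_mcs(mcm: MCModel, sets: list[MetaboliteSet], selection: str = "fdr0.05",
               n_null: int = 20, seed: int = 0) -> np.ndarray:
    """Pick MC indices: 'topN' by variance explained, 'all', or 'fdrX' for
    MCs enriched for >= 1 metabolite set at FDR X."""
    if selection == "all":
        return np.arange(mcm.n_mcs)
    if selection.startswith("top"):
        k = int(selection[3:])
        return np.arange(min(k, mcm.n_mcs))
    if selection.startswith("fdr"):
        level = float(selection[3:])
        enr = mcm.enrichment
        if enr is None:
            enr = mc_set_enrichment(mcm, sets, n_null=n_null, seed=seed)
            mcm.enrichment = enr
        hit = enr[enr["fdr"] <= level]["mc"].unique()
        return np.sort(hit)
    raise ValidationError(f"unknown MC selection {selection!r}")


@dataclass
class AnnotationMatrix:
    """Signals x metabolite-sets reconstituted membership scores.

    ``scores`` holds Spearman correlations in [-1, 1]; ``loo_mask`` marks
    (signal, set) cells recomputed with the signal's metabolite left out of
    the set; ``label_p`` is filled by :func:`label_confidence`.
    """

    scores: pd.DataFrame  # index: signal ids, columns: set ids
    sets: list[MetaboliteSet]
    mc_subset: np.ndarray
    loo_mask: pd.DataFrame
    known_names: pd.Series
    label_p: pd.Series | None = None

    @property
    def set_ids(self) -> list[str]:
        return list(self.scores.columns)

    def set_by_id(self, set_id: str) -> MetaboliteSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return stats.rankdata(X, axis=1)


def _row_standardize(R: np.ndarray) -> np.ndarray:
    Rc = R - R.mean(axis=1, keepdims=True)
    s = np.sqrt((Rc**2).sum(axis=1, keepdims=True))
    s[s == 0] = np.nan
    return Rc / s


def reconstitute(
    mcm: MCModel, sets: list[MetaboliteSet], mc_filter: np.ndarray
) -> AnnotationMatrix:
    """Build the signal x metabolite-set annotation matrix.

    For each set, the signed rank-sum z profile over the selected MCs is
    correlated (Spearman) with each signal's loading profile.  For a known
    metabolite curated in the set, the z profile is recomputed without that
    metabolite before scoring it (leave-one-out), so non-member scores are
    untouched.
    """
    mc_filter = np.asarray(mc_filter, dtype=int)
    if len(mc_filter) < 3:
        raise ValidationError("need at least 3 selected MCs")
    K, names = mcm.known_loadings()
    Ksel = K[:, mc_filter]
    M = _membership_matrix(sets, names)
    Z, _ = ranksum_z_matrix(Ksel, M)  # (n_mc_sel, n_sets)
    Z = Z.T  # (n_sets, n_mc_sel)
    L = mcm.loadings[:, mc_filter]  # (n_signals, n_mc_sel)
    Rs = _row_standardize(_rank_rows(L))
    Rz = _row_standardize(_rank_rows(Z))
    scores = Rs @ Rz.T  # (n_signals, n_sets)
    loo = np.zeros_like(scores, dtype=bool)
    sig_index = {s: i for i, s in enumerate(mcm.signal_ids)}
    name_row = {n: i for i, n in enumerate(names)}
    known_sig = {n: s for s, n in mcm.known_names.items()}
    for j, st in enumerate(sets):
        present = [m for m in st.members if m in name_row]
        for m in present:
            mask = M[:, j].copy()
            mask[name_row[m]] = False
            keep = np.ones(len(names), dtype=bool)
            keep[name_row[m]] = False
            n_in = int(mask[keep].sum())
            if n_in == 0 or n_in == int(keep.sum()):
                continue
            z_loo, _ = ranksum_z_matrix(Ksel[keep], mask[keep, None])
            z_loo = z_loo[:, 0]
            i = sig_index[known_sig[m]]
            rz = _row_standardize(_rank_rows(z_loo[None, :]))[0]
            scores[i, j] = float(Rs[i] @ rz)
            loo[i, j] = True
    scores = np.clip(scores, -1.0, 1.0)
    set_ids = [s.set_id for s in sets]
    return AnnotationMatrix(
        scores=pd.DataFrame(scores, index=mcm.signal_ids, columns=set_ids),
        sets=list(sets),
        mc_subset=mc_filter,
        loo_mask=pd.DataFrame(loo, index=mcm.signal_ids, columns=set_ids),
        known_names=mcm.known_names,
    )


def annotation_pvalues(matrix: AnnotationMatrix, k: int | None = None) -> pd.DataFrame:
    """Two-sided p-values for the Spearman scores via the t approximation
    t = r sqrt((k-2)/(1-r^2)) on k-2 degrees of freedom (|r| = 1 -> p = 0)."""
    k = k if k is not None else len(matrix.mc_subset)
    if k < 3:
        raise ValidationError("need k >= 3 MCs")
    r = matrix.scores.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((k - 2) / (1 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), k - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return pd.DataFrame(p, index=matrix.scores.index, columns=matrix.scores.columns)


def classification_auc(
    matrix: AnnotationMatrix,
    sets: list[MetaboliteSet] | None = None,
    pvalues: pd.DataFrame | None = None,
    permute_with_seed: int | None = None,
):
    """AUC for classifying known metabolites into their original sets.

    Positives are (known, set) pairs with the known curated in the set; the
    classification score is -p from :func:`annotation_pvalues`.  With
    ``permute_with_seed`` the known rows of the matrix are shuffled first
    (null comparison).  Returns (auc, labels, scores).
    """
    sets = sets or matrix.sets
    pvals = pvalues if pvalues is not None else annotation_pvalues(matrix)
    known_sigs = list(matrix.known_names.index)
    names = list(matrix.known_names)
    P = pvals.loc[known_sigs].to_numpy()
    if permute_with_seed is not None:
        rng = np.random.default_rng(permute_with_seed)
        P = P[rng.permutation(P.shape[0])]
    M = _membership_matrix(sets, names)
    set_ids = [s.set_id for s in sets]
    col_idx = [list(pvals.columns).index(sid) for sid in set_ids]
    labels = M.ravel()
    scores = -P[:, col_idx].ravel()
    if labels.all() or not labels.any():
        raise ValidationError("need both positive and negative (metabolite, set) pairs")
    return float(roc_auc_score(labels, scores)), labels, scores


def label_confidence(matrix: AnnotationMatrix, sets: list[MetaboliteSet] | None = None) -> pd.Series:
    """Per-set label confidence score.

    Two-tailed rank-sum p testing whether the absolute reconstituted scores
    of a set's originally curated members exceed those of the other known
    metabolites.  Sets with p < 0.05 are the confidently reconstituted
    ("filtered") annotation.
    """
    sets = sets or matrix.sets
    known_sigs = list(matrix.known_names.index)
    names = list(matrix.known_names)
    A = np.abs(matrix.scores.loc[known_sigs].to_numpy())
    M = _membership_matrix(sets, names)
    set_ids = [s.set_id for s in sets]
    col_idx = [list(matrix.scores.columns).index(sid) for sid in set_ids]
    ps = np.ones(len(sets))
    for j, cj in enumerate(col_idx):
        mask = M[:, j]
        if not mask.any() or mask.all():
            continue
        _, P = ranksum_z_matrix(A[:, [cj]], mask[:, None])
        ps[j] = P[0, 0]
    out = pd.Series(ps, index=set_ids, name="label_p")
    matrix.label_p = out
    return out
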