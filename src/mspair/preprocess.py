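"""Simplified QC and transformation pipeline for profiling datasets.

Steps, in the order they are normally applied:

1. optional natural-log transform,
2. MAD-based outlier masking per signal,
3. missingness filtering (signals first, then samples),
4. chained linear-regression imputation of remaining missing values,
5. covariate adjustment (OLS residuals),
6. rank-based inverse normal transform to abundance z-scores.

The outlier and imputation steps are deliberately simple, deterministic
surrogates for platform-specific QC and multiple-imputation pipelines: the
downstream matching and pathway procedures only consume z-scored inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import ols_association
from .datatypes import ProfilingDataset, ValidationError

logger = logging.getLogger("mspair")

__all__ = [
    "PreprocessConfig",
    "filter_missingness",
    "mask_outliers",
    "impute_missing_chained",
    "adjust_covariates",
    "inverse_normal_transform",
    "compute_phenotype_zscores",
    "associate_signals",
    "run_pipeline",
]

MAD_SCALE = 1.4826  # consistency factor for normal data


@dataclass
class PreprocessConfig:
    """Tunable QC parameters.

    ``signal_missing_max`` / ``sample_missing_max`` are the maximum tolerated
    missing fractions (signals and samples above them are dropped);
    ``outlier_mad_k`` is the robust-z cutoff for point masking;
    ``impute_iterations`` / ``impute_predictors_max`` control the chained
    imputer.
    """

    sample_missing_max: float = 0.5
    signal_missing_max: float = 0.5
    outlier_mad_k: float = 5.0
    impute_iterations: int = 5
    impute_predictors_max: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.sample_missing_max, self.signal_missing_max):
            if not 0 <= f <= 1:
                raise ValidationError("missingness thresholds must be in [0, 1]")
        if self.outlier_mad_k <= 0:
            raise ValidationError("outlier_mad_k must be positive")


def filter_missingness(ds: ProfilingDataset, cfg: PreprocessConfig):
    """Drop signals then samples exceeding the configured missing fractions.

    Signals are filtered first; sample missingness is then computed on the
    retained signals only.  Returns (filtered dataset, report dict with the
    dropped ids).
    """
    miss = ds.abundance.isna()
    sig_frac = miss.mean(axis=0)
    keep_sig = sig_frac.index[sig_frac <= cfg.signal_missing_max]
    dropped_sig = sorted(set(ds.signal_ids) - set(keep_sig))
    if len(keep_sig) == 0:
        raise ValidationError("all signals dropped by missingness filter")
    sub = ds.abundance[keep_sig]
    samp_frac = sub.isna().mean(axis=1)
    keep_samp = samp_frac.index[samp_frac <= cfg.sample_missing_max]
    dropped_samp = sorted(set(ds.sample_ids) - set(keep_samp))
    out = ds.subset_signals(keep_sig).subset_samples(keep_samp)
    logger.info(
        "missingness filter: dropped %d signals, %d samples",
        len(dropped_sig),
        len(dropped_samp),
    )
    return out, {"dropped_signals": dropped_sig, "dropped_samples": dropped_samp}


def mask_outliers(ds: ProfilingDataset, cfg: PreprocessConfig) -> ProfilingDataset:
    """Set to missing any point with |x - median| > k * 1.4826 * MAD.

    Signals with MAD = 0 (near-constant) are skipped with a warning rather
    than fully masked.
    """
    ab = ds.abundance.copy()
    X = ab.to_numpy()
    med = np.nanmedian(X, axis=0)
    mad = np.nanmedian(np.abs(X - med), axis=0)
    skipped = []
    for j, sid in enumerate(ab.columns):
        if not np.isfinite(mad[j]) or mad[j] == 0:
            skipped.append(sid)
            continue
        cut = cfg.outlier_mad_k * MAD_SCALE * mad[j]
        mask = np.abs(X[:, j] - med[j]) > cut
        X[mask, j] = np.nan
    if skipped:
        logger.warning("outlier masking skipped %d signals with MAD = 0", len(skipped))
    return ds.copy_with(pd.DataFrame(X, index=ab.index, columns=ab.columns))


def impute_missing_chained(ds: ProfilingDataset, cfg: PreprocessConfig) -> ProfilingDataset:
    """Fill missing entries by chained ordinary-least-squares prediction.

    Each signal's missing values are predicted from its most-correlated
    other signals (at most ``impute_predictors_max``, correlation measured on
    the mean-initialized matrix), cycling ``impute_iterations`` times.
    Observed entries are never altered and the result is deterministic.
    """
    ab = ds.abundance
    obs_counts = ab.notna().sum(axis=0)
    bad = sorted(obs_counts.index[obs_counts < 2])
    if bad:
        raise ValidationError(f"signals with < 2 observed values: {bad[:5]}")
    X = ab.to_numpy().copy()
    missing = np.isnan(X)
    if not missing.any():
        return ds.copy_with(ab.copy())
    col_means = np.nanmean(X, axis=0)
    filled = np.where(missing, col_means[None, :], X)
    targets = np.where(missing.any(axis=0))[0]
    for _ in range(cfg.impute_iterations):
        # correlations on the current filled matrix
        Z = filled - filled.mean(axis=0)
        norms = np.sqrt((Z**2).sum(axis=0))
        norms[norms == 0] = 1.0
        Zn = Z / norms
        C = Zn.T @ Zn
        np.fill_diagonal(C, 0.0)
        for j in targets:
            rows = missing[:, j]
            order = np.argsort(-np.abs(C[:, j]))
            k = min(cfg.impute_predictors_max, len(order))
            pred = order[:k]
            A = np.column_stack([np.ones(filled.shape[0]), filled[:, pred]])
            obs = ~rows
            coef, *_ = np.linalg.lstsq(A[obs], X[obs, j], rcond=None)
            filled[rows, j] = A[rows] @ coef
    filled[~missing] = X[~missing]
    return ds.copy_with(pd.DataFrame(filled, index=ab.index, columns=ab.columns))


def _residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, C]; raises on collinear covariates."""
    A = np.column_stack([np.ones(len(y)), C])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValidationError("collinear covariate set")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ coef


def adjust_covariates(ds: ProfilingDataset, covariate_names: list[str]) -> ProfilingDataset:
    """Replace each signal by its OLS residuals on intercept + covariates."""
    if ds.covariates is None:
        raise ValidationError("dataset has no covariate table")
    missing = [c for c in covariate_names if c not in ds.covariates.columns]
    if missing:
        raise ValidationError(f"covariates absent: {missing}")
    C = ds.covariates[covariate_names].to_numpy(dtype=float)
    if np.isnan(C).any():
        raise ValidationError("covariates contain missing values")
    ab = ds.abundance.to_numpy()
    out = np.empty_like(ab)
    A = np.column_stack([np.ones(ab.shape[0]), C])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValidationError("collinear covariate set")
    pinv = np.linalg.pinv(A)
    for j in range(ab.shape[1]):
        y = ab[:, j]
        obs = ~np.isnan(y)
        if obs.all():
            out[:, j] = y - A @ (pinv @ y)
        else:
            out[:, j] = np.nan
            coef, *_ = np.linalg.lstsq(A[obs], y[obs], rcond=None)
            out[obs, j] = y[obs] - A[obs] @ coef
    return ds.copy_with(pd.DataFrame(out, index=ds.abundance.index, columns=ds.abundance.columns))


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    z_i = Phi^-1((r_i - 3/8) / (n + 1/4)) where r_i is the 1-based average
    rank among non-missing values; missing entries stay missing.  All-equal
    input maps to all zeros with a warning.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    obs = ~np.isnan(v)
    n = int(obs.sum())
    if n < 2:
        raise ValidationError("need at least 2 non-missing values")
    x = v[obs]
    if np.all(x == x[0]):
        logger.warning("inverse normal transform: all values identical, returning zeros")
        out[obs] = 0.0
        return out
    ranks = stats.rankdata(x)
    out[obs] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def transform_to_zscores(ds: ProfilingDataset) -> ProfilingDataset:
    """Apply the inverse normal transform to every signal column."""
    ab = ds.abundance.to_numpy()
    out = np.column_stack([inverse_normal_transform(ab[:, j]) for j in range(ab.shape[1])])
    return ds.copy_with(pd.DataFrame(out, index=ds.abundance.index, columns=ds.abundance.columns))


def compute_phenotype_zscores(pheno, covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Phenotype z-scores: residualize on covariates, then rank-INT."""
    y = np.asarray(pheno, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if np.isnan(C).any():
        raise ValidationError("covariates contain missing values")
    resid = _residualize(y, C)
    if np.allclose(resid, 0.0, atol=1e-10 * max(1.0, float(np.abs(y).max()))):
        logger.warning("phenotype fully explained by covariates; z-scores are all zero")
        return np.zeros_like(resid)
    return inverse_normal_transform(resid)


def associate_signals(ds: ProfilingDataset, pheno_z) -> pd.DataFrame:
    """Per-signal OLS of the phenotype z-score on signal abundance.

    Returns a DataFrame (signal_id, beta, se, p, significant) where the
    significance flag applies the Bonferroni threshold 0.05 / n_signals.
    """
    y = np.asarray(pheno_z, dtype=float)
    X = ds.abundance.to_numpy()
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValidationError("association requires complete data")
    beta, se, p = ols_association(y, X)
    thr = 0.05 / ds.n_signals
    return pd.DataFrame(
        {
            "signal_id": ds.signal_ids,
            "beta": beta,
            "se": se,
            "p": p,
            "significant": p < thr,
        }
    )


def run_pipeline(
    ds: ProfilingDataset,
    cfg: PreprocessConfig,
    covariate_names: list[str] | None = None,
    log_transform: bool = False,
):
    """Full QC chain; returns (z-scored dataset, QC report)."""
    if log_transform:
        ds = ds.copy_with(np.log(ds.abundance))
    ds = mask_outliers(ds, cfg)
    ds, report = filter_missingness(ds, cfg)
    ds = impute_missing_chained(ds, cfg)
    if covariate_names:
        ds = adjust_covariates(ds, covariate_names)
    ds = transform_to_zscores(ds)
    return ds, report
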