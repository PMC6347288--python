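"""Cross-dataset signal matching from m/z agreement and imputation-based
correlation.

The matcher pairs up signals measured in two untargeted LC-MS datasets
without using retention time.  A candidate pair must first agree in m/z:
the difference of the two m/z values must fall within ``tolerance`` of some
adduct-shift difference *d* (``d = 0`` for same-adduct matches; ionization
modes and adduct ions extend the allowed set of *d* values).  Candidates are
then ranked by the Pearson correlation between one signal's observed
abundances and the other's abundances imputed across datasets via linear
models built on the known metabolites shared (by name) between the two
datasets.  An RT-shift baseline matcher and a calibration harness that
treats each shared known as an unmatched signal are included.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import ProfilingDataset, ValidationError

logger = logging.getLogger("mspair")

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "Adduct",
    "AdductTable",
    "MatchConfig",
    "MatchResult",
    "adduct_shift_set",
    "mz_agree",
    "candidate_pairs",
    "CrossImputer",
    "fit_imputation_model",
    "impute_across",
    "pair_correlation",
    "match_signals",
    "match_by_rt",
    "calibrate_matching",
    "default_setting_grid",
]

# monoisotopic ion masses (Da)
ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.007276466
NH4_MASS = 18.033823  # N + 4H - e
NA_MASS = 22.989218  # Na - e


@dataclass(frozen=True)
class Adduct:
    """A singly charged adduct ion: observed m/z = neutral mass + shift."""

    name: str
    mode: str
    shift: float
    charge: int = 1


def _default_adducts() -> tuple[Adduct, ...]:
    return (
        Adduct("M+", "positive", -ELECTRON_MASS),
        Adduct("[M+H]+", "positive", PROTON_MASS),
        Adduct("[M+NH4]+", "positive", NH4_MASS),
        Adduct("[M+Na]+", "positive", NA_MASS),
        Adduct("[M-H]-", "negative", -PROTON_MASS),
    )


@dataclass(frozen=True)
class AdductTable:
    """User-extensible table of adduct ions considered during matching.

    ``primary`` names the default adduct per mode used in the "no_adduct"
    setting (the most common ion of each mode).
    """

    entries: tuple[Adduct, ...] = field(default_factory=_default_adducts)
    primary: tuple[tuple[str, str], ...] = (
        ("positive", "[M+H]+"),
        ("negative", "[M-H]-"),
    )

    def for_mode(self, mode: str) -> list[Adduct]:
        out = [a for a in self.entries if a.mode == mode]
        if not out:
            raise ValidationError(f"unknown ionization mode {mode!r}")
        return out

    def primary_for_mode(self, mode: str) -> Adduct:
        names = dict(self.primary)
        if mode not in names:
            raise ValidationError(f"unknown ionization mode {mode!r}")
        name = names[mode]
        for a in self.entries:
            if a.mode == mode and a.name == name:
                return a
        raise ValidationError(f"primary adduct {name!r} missing for mode {mode!r}")


ADDUCT_SETTINGS = ("no_adduct", "adduct", "combined")
CORRELATION_SETTINGS = ("dataset1", "dataset2", "all")
MATCH_TYPES = ("multiple", "unique", "reciprocal")
PARTITIONS = ("within_method", "across_method")


@dataclass(frozen=True)
class MatchConfig:
    """Parameter grid point for the matcher."""

    adduct_setting: str = "adduct"
    correlation_setting: str = "all"
    match_type: str = "reciprocal"
    partition: str = "within_method"
    correlation_cutoff: float | None = None
    tolerance: float = 0.005
    method_aliases: tuple[tuple[str, str], ...] = (("LIPID", "C8-pos"),)
    adduct_table: AdductTable = field(default_factory=AdductTable)

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.adduct_setting not in ADDUCT_SETTINGS:
            raise ValidationError(f"adduct_setting must be one of {ADDUCT_SETTINGS}")
        if self.correlation_setting not in CORRELATION_SETTINGS:
            raise ValidationError(f"correlation_setting must be one of {CORRELATION_SETTINGS}")
        if self.match_type not in MATCH_TYPES:
            raise ValidationError(f"match_type must be one of {MATCH_TYPES}")
        if self.partition not in PARTITIONS:
            raise ValidationError(f"partition must be one of {PARTITIONS}")
        if self.correlation_cutoff is not None and not -1 <= self.correlation_cutoff <= 1:
            raise ValidationError("correlation_cutoff must be in [-1, 1]")

    def canonical_method(self, method: str | None) -> str | None:
        return dict(self.method_aliases).get(method, method)


@dataclass
class MatchResult:
    """Matched signal pairs: signal1_id, signal2_id, r, d_used, direction."""

    pairs: pd.DataFrame
    config: MatchConfig

    def __len__(self) -> int:
        return len(self.pairs)


def adduct_shift_set(mode1: str, mode2: str, setting: str, table: AdductTable | None = None):
    """Allowed m/z-difference values *d* for a signal pair with the given
    ionization modes.

    "no_adduct" uses only the primary adduct of each mode (d = shift1 -
    shift2); "adduct" enumerates all adduct pairs.  The set is de-duplicated.
    """
    table = table or AdductTable()
    if setting == "no_adduct":
        pairs = [(table.primary_for_mode(mode1), table.primary_for_mode(mode2))]
    elif setting in ("adduct", "combined"):
        pairs = list(itertools.product(table.for_mode(mode1), table.for_mode(mode2)))
    else:
        raise ValidationError(f"unknown adduct setting {setting!r}")
    ds = sorted({round(a1.shift - a2.shift, 9) for a1, a2 in pairs})
    return np.array(ds)


def mz_agree(mz1, mode1, mz2, mode2, setting, cfg: MatchConfig):
    """Check whether two m/z values agree under an adduct setting.

    Returns (agrees, d_used) where d_used is the allowed shift difference
    minimizing |(mz1 - mz2) - d|; missing m/z yields (False, None).
    """
    if mz1 is None or mz2 is None or not np.isfinite(mz1) or not np.isfinite(mz2):
        return False, None
    base = "no_adduct" if setting == "no_adduct" else "adduct"
    if setting == "combined":
        ok, d = mz_agree(mz1, mode1, mz2, mode2, "no_adduct", cfg)
        if ok:
            return ok, d
        base = "adduct"
    ds = adduct_shift_set(mode1, mode2, base, cfg.adduct_table)
    resid = np.abs((mz1 - mz2) - ds)
    j = int(np.argmin(resid))
    if resid[j] <= cfg.tolerance:
        return True, float(ds[j])
    return False, None


def _partition_groups(ds1: ProfilingDataset, ds2: ProfilingDataset, cfg: MatchConfig):
    """Yield (idx1, idx2, mode1, mode2) index groups respecting the partition
    setting, restricted to signals with m/z."""
    m1 = ds1.meta
    m2 = ds2.meta
    ok1 = m1["mz"].notna().to_numpy()
    ok2 = m2["mz"].notna().to_numpy()
    if cfg.partition == "within_method":
        meth1 = m1["method"].map(lambda m: cfg.canonical_method(m) if pd.notna(m) else m)
        meth2 = m2["method"].map(lambda m: cfg.canonical_method(m) if pd.notna(m) else m)
        keys = sorted(
            set(meth1[ok1].dropna()) & set(meth2[ok2].dropna()), key=str
        )
        for key in keys:
            g1 = np.where(ok1 & (meth1 == key).to_numpy())[0]
            g2 = np.where(ok2 & (meth2 == key).to_numpy())[0]
            yield g1, g2
    else:
        yield np.where(ok1)[0], np.where(ok2)[0]


def candidate_pairs(ds1: ProfilingDataset, ds2: ProfilingDataset, cfg: MatchConfig,
                    query_signals: list[str] | None = None) -> pd.DataFrame:
    """All m/z-agreeing (signal1, signal2) pairs under the configured adduct
    and partition settings.

    In the "combined" setting the per-signal no-adduct candidate list is
    used; the full adduct list is consulted only when it is empty.  Returns a
    DataFrame (signal1_id, signal2_id, d_used, mz_resid).
    """
    m1, m2 = ds1.meta, ds2.meta
    sig1 = np.array(ds1.signal_ids)
    sig2 = np.array(ds2.signal_ids)
    qset = None if query_signals is None else set(query_signals)
    rows: list[tuple] = []
    for g1, g2 in _partition_groups(ds1, ds2, cfg):
        if len(g1) == 0 or len(g2) == 0:
            continue
        mz2 = m2["mz"].to_numpy(dtype=float)[g2]
        mode2 = m2["mode"].to_numpy()[g2]
        for i in g1:
            sid1 = sig1[i]
            if qset is not None and sid1 not in qset:
                continue
            mz1 = float(m1["mz"].iloc[i])
            mode1 = m1["mode"].iloc[i]
            found = []
            for setting in (
                ("no_adduct",) if cfg.adduct_setting == "no_adduct"
                else ("adduct",) if cfg.adduct_setting == "adduct"
                else ("no_adduct", "adduct")
            ):
                # group candidates by the mode of the dataset-2 signal
                for mode in pd.unique(mode2):
                    dset = adduct_shift_set(mode1, mode, setting, cfg.adduct_table)
                    sel = mode2 == mode
                    diffs = mz1 - mz2[sel]
                    resid = np.abs(diffs[:, None] - dset[None, :])
                    jmin = np.argmin(resid, axis=1)
                    rmin = resid[np.arange(len(diffs)), jmin]
                    hit = rmin <= cfg.tolerance
                    for k in np.where(hit)[0]:
                        j = g2[np.where(sel)[0][k]]
                        found.append((sid1, sig2[j], float(dset[jmin[k]]), float(rmin[k])))
                if found:
                    break  # combined: suppress adduct list when no_adduct hit
            rows.extend(found)
    return pd.DataFrame(rows, columns=["signal1_id", "signal2_id", "d_used", "mz_resid"])


# ---------------------------------------------------------------------------
# imputation across datasets


@dataclass
class ImputationModel:
    """Linear model predicting one signal from shared known metabolites.

    Predictors are referenced by known-metabolite name so the model can be
    applied to any dataset profiling those metabolites.
    """

    target_signal_id: str
    predictor_names: list[str]
    intercept: float
    coef: np.ndarray

    def predict(self, ds: ProfilingDataset) -> np.ndarray:
        cols = []
        for name in self.predictor_names:
            try:
                cols.append(ds.abundance[ds.signal_of_known(name)].to_numpy(dtype=float))
            except KeyError as e:
                raise ValidationError(f"predictor metabolite {name!r} absent from target dataset") from e
        X = np.column_stack(cols) if cols else np.empty((ds.n_samples, 0))
        return self.intercept + X @ self.coef


def shared_known_names(ds1: ProfilingDataset, ds2: ProfilingDataset) -> list[str]:
    """Known metabolites present (by exact name) in both datasets."""
    return sorted(set(ds1.known_names) & set(ds2.known_names))


def fit_imputation_model(
    source: ProfilingDataset, target_signal_id: str, shared_knowns: list[str]
) -> ImputationModel:
    """OLS fit of a source-dataset signal on the shared known metabolites.

    If the target signal is itself a shared known it is removed from the
    predictor set (leave-one-out), so a metabolite is never predicted from
    its own measurements.  Rank-deficient designs get the minimum-norm
    solution.
    """
    own = source.meta.loc[target_signal_id, "known_name"]
    predictors = [k for k in shared_knowns if not (pd.notna(own) and k == own)]
    if len(predictors) < 2:
        raise ValidationError("need at least 2 predictor metabolites")
    X = np.column_stack(
        [source.abundance[source.signal_of_known(k)].to_numpy(dtype=float) for k in predictors]
    )
    y = source.abundance[target_signal_id].to_numpy(dtype=float)
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return ImputationModel(target_signal_id, predictors, float(coef[0]), coef[1:])


def impute_across(source: ProfilingDataset, target_ds: ProfilingDataset,
                  model: ImputationModel) -> np.ndarray:
    """Apply a source-fitted model to the target dataset's shared knowns."""
    return model.predict(target_ds)


class CrossImputer:
    """Batch imputation of every signal of each dataset into the other.

    Fits, per dataset, one multi-response least-squares model of all signals
    on the shared known metabolites (each shared-known signal's own column is
    refit without itself), then evaluates the predictions on the partner
    dataset.  ``imputed_2_in_1`` has one column per dataset-2 signal over
    dataset-1 samples, and vice versa.
    """

    def __init__(self, ds1: ProfilingDataset, ds2: ProfilingDataset):
        self.ds1, self.ds2 = ds1, ds2
        self.shared = shared_known_names(ds1, ds2)
        if len(self.shared) < 3:
            raise ValidationError("need at least 3 shared known metabolites")
        self.imputed_1_in_2 = self._impute(ds1, ds2)
        self.imputed_2_in_1 = self._impute(ds2, ds1)

    def _impute(self, src: ProfilingDataset, dst: ProfilingDataset) -> pd.DataFrame:
        names = self.shared
        src_cols = [src.signal_of_known(k) for k in names]
        dst_cols = [dst.signal_of_known(k) for k in names]
        Xs = src.abundance[src_cols].to_numpy(dtype=float)
        Xd = dst.abundance[dst_cols].to_numpy(dtype=float)
        Y = src.abundance.to_numpy(dtype=float)
        if np.isnan(Xs).any() or np.isnan(Y).any() or np.isnan(Xd).any():
            raise ValidationError("imputation requires complete (imputed) data")
        A = np.column_stack([np.ones(Xs.shape[0]), Xs])
        B, *_ = np.linalg.lstsq(A, Y, rcond=None)  # (1+k, p_src)
        Ad = np.column_stack([np.ones(Xd.shape[0]), Xd])
        pred = Ad @ B
        # leave-one-out refit for each shared known's own signal
        col_index = {c: j for j, c in enumerate(src.signal_ids)}
        for pos, (name, scol) in enumerate(zip(names, src_cols)):
            keep = [j for j in range(len(names)) if j != pos]
            Aloo = np.column_stack([np.ones(Xs.shape[0]), Xs[:, keep]])
            coef, *_ = np.linalg.lstsq(Aloo, Y[:, col_index[scol]], rcond=None)
            Adloo = np.column_stack([np.ones(Xd.shape[0]), Xd[:, keep]])
            pred[:, col_index[scol]] = Adloo @ coef
        return pd.DataFrame(pred, index=dst.abundance.index, columns=src.abundance.columns)


def _corr_one_to_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between vector x and each column of Y; NaN if degenerate."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    xs = np.sqrt((xc**2).sum())
    ys = np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ Yc) / (xs * ys)
    r[~np.isfinite(r)] = np.nan
    return r


def pair_correlation(s1: str, s2: str, setting: str, imputer: CrossImputer) -> float:
    """Cross-dataset correlation for one (dataset-1, dataset-2) signal pair.

    dataset1: observed s1 vs imputed s2 over dataset-1 samples; dataset2:
    imputed s1 vs observed s2 over dataset-2 samples; all: both sample sets
    concatenated, observed where native and imputed otherwise.
    """
    obs1 = imputer.ds1.abundance[s1].to_numpy(dtype=float)
    obs2 = imputer.ds2.abundance[s2].to_numpy(dtype=float)
    imp2 = imputer.imputed_2_in_1[s2].to_numpy(dtype=float)
    imp1 = imputer.imputed_1_in_2[s1].to_numpy(dtype=float)
    if setting == "dataset1":
        x, y = obs1, imp2
    elif setting == "dataset2":
        x, y = imp1, obs2
    elif setting == "all":
        x, y = np.concatenate([obs1, imp1]), np.concatenate([imp2, obs2])
    else:
        raise ValidationError(f"unknown correlation setting {setting!r}")
    r = _corr_one_to_many(x, y[:, None])[0]
    return float(r)


def _score_candidates(cands: pd.DataFrame, imputer: CrossImputer, setting: str,
                      flip: bool) -> pd.DataFrame:
    """Attach the ranking correlation r to each candidate pair.

    ``flip`` indicates the query side is dataset 2 (matching 2 -> 1); the
    correlation settings are interpreted relative to the query dataset:
    "dataset1" correlates over the query's samples, "dataset2" over the
    candidate dataset's samples.
    """
    if cands.empty:
        return cands.assign(r=pd.Series(dtype=float))
    if not flip:
        obs_q = imputer.ds1.abundance
        obs_c = imputer.ds2.abundance
        imp_c_in_q = imputer.imputed_2_in_1
        imp_q_in_c = imputer.imputed_1_in_2
    else:
        obs_q = imputer.ds2.abundance
        obs_c = imputer.ds1.abundance
        imp_c_in_q = imputer.imputed_1_in_2
        imp_q_in_c = imputer.imputed_2_in_1
    rs = np.full(len(cands), np.nan)
    for sid, grp in cands.groupby("signal1_id", sort=False):
        j = grp["signal2_id"].tolist()
        if setting == "dataset1":
            x = obs_q[sid].to_numpy(dtype=float)
            Y = imp_c_in_q[j].to_numpy(dtype=float)
        elif setting == "dataset2":
            x = imp_q_in_c[sid].to_numpy(dtype=float)
            Y = obs_c[j].to_numpy(dtype=float)
        else:
            x = np.concatenate(
                [obs_q[sid].to_numpy(dtype=float), imp_q_in_c[sid].to_numpy(dtype=float)]
            )
            Y = np.vstack(
                [imp_c_in_q[j].to_numpy(dtype=float), obs_c[j].to_numpy(dtype=float)]
            )
        rs[cands.index.get_indexer(grp.index)] = _corr_one_to_many(x, Y)
    out = cands.assign(r=rs)
    n_bad = int(out["r"].isna().sum())
    if n_bad:
        logger.warning("%d candidate pairs skipped (degenerate correlation)", n_bad)
    return out.dropna(subset=["r"])


def _select_best(scored: pd.DataFrame, by: str, ascending: bool) -> pd.DataFrame:
    """Per query signal, pick the best candidate.

    Ties on the ranking value are broken by smaller m/z residual, then by
    lexicographic candidate id.
    """
    if scored.empty:
        return scored
    s = scored.sort_values(
        [by, "mz_resid", "signal2_id"], ascending=[ascending, True, True], kind="mergesort"
    )
    return s.groupby("signal1_id", sort=False).head(1).reset_index(drop=True)


def _unique_filter(best: pd.DataFrame, by: str, ascending: bool) -> pd.DataFrame:
    """Keep, per candidate signal, only the best-ranked query signal."""
    if best.empty:
        return best
    s = best.sort_values(
        [by, "mz_resid", "signal1_id"], ascending=[ascending, True, True], kind="mergesort"
    )
    return s.groupby("signal2_id", sort=False).head(1).reset_index(drop=True)


def _match_direction(ds_q, ds_c, cfg, imputer, flip, query_signals=None) -> pd.DataFrame:
    cands = candidate_pairs(ds_q, ds_c, cfg, query_signals=query_signals)
    scored = _score_candidates(cands, imputer, cfg.correlation_setting, flip)
    best = _select_best(scored, by="r", ascending=False)
    if cfg.correlation_cutoff is not None and not best.empty:
        best = best[best["r"] > cfg.correlation_cutoff].reset_index(drop=True)
    return best


def match_signals(
    ds1: ProfilingDataset,
    ds2: ProfilingDataset,
    cfg: MatchConfig,
    imputer: CrossImputer | None = None,
    query_signals1: list[str] | None = None,
    query_signals2: list[str] | None = None,
) -> MatchResult:
    """Match dataset-1 signals to dataset-2 signals.

    "multiple" keeps, per dataset-1 signal, the m/z-agreeing candidate with
    maximal correlation; "unique" additionally keeps only the best dataset-1
    signal mapped to each dataset-2 signal; "reciprocal" intersects the two
    directed unique maps.  ``query_signals*`` optionally restrict which
    signals are treated as queries (used by the calibration harness).
    """
    imputer = imputer or CrossImputer(ds1, ds2)
    fwd = _match_direction(ds1, ds2, cfg, imputer, flip=False, query_signals=query_signals1)
    if cfg.match_type == "multiple":
        pairs = fwd.assign(direction="1->2")
    elif cfg.match_type == "unique":
        pairs = _unique_filter(fwd, by="r", ascending=False).assign(direction="1->2")
    else:  # reciprocal
        uniq_fwd = _unique_filter(fwd, by="r", ascending=False)
        rev = _match_direction(ds2, ds1, cfg, imputer, flip=True, query_signals=query_signals2)
        uniq_rev = _unique_filter(rev, by="r", ascending=False)
        rev_pairs = set(zip(uniq_rev["signal2_id"], uniq_rev["signal1_id"]))
        keep = [
            (s1, s2) in rev_pairs
            for s1, s2 in zip(uniq_fwd["signal1_id"], uniq_fwd["signal2_id"])
        ]
        pairs = uniq_fwd[keep].assign(direction="both")
    pairs = pairs.sort_values("signal1_id").reset_index(drop=True)
    pairs = pairs[["signal1_id", "signal2_id", "r", "d_used", "mz_resid", "direction"]]
    logger.info("matched %d pairs (%s)", len(pairs), cfg.match_type)
    return MatchResult(pairs, cfg)


# ---------------------------------------------------------------------------
# RT-shift baseline


def _rt_shift_models(ds1, ds2, cfg):
    """Per-method (or global) OLS of dataset-2 RT on dataset-1 RT over shared
    knowns with RT in both datasets."""
    shared = shared_known_names(ds1, ds2)
    rows = []
    for name in shared:
        s1, s2 = ds1.signal_of_known(name), ds2.signal_of_known(name)
        rt1, rt2 = ds1.meta.loc[s1, "rt"], ds2.meta.loc[s2, "rt"]
        meth = cfg.canonical_method(ds1.meta.loc[s1, "method"])
        if pd.notna(rt1) and pd.notna(rt2):
            rows.append((meth, float(rt1), float(rt2)))
    models = {}
    keys = {r[0] for r in rows} if cfg.partition == "within_method" else {None}
    for key in keys:
        pts = [(a, b) for m, a, b in rows if key is None or m == key]
        if len(pts) < 2:
            continue
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        A = np.column_stack([np.ones(len(x)), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        models[key] = coef
    if not models:
        raise ValidationError("need >= 2 shared knowns with RT to fit the shift model")
    return models


def match_by_rt(
    ds1: ProfilingDataset,
    ds2: ProfilingDataset,
    cfg: MatchConfig,
    query_signals1: list[str] | None = None,
    query_signals2: list[str] | None = None,
) -> MatchResult:
    """m/z + RT baseline: among m/z-agreeing candidates pick the one whose
    observed RT is closest to the RT predicted by a linear shift model fit on
    shared knowns (one model per profiling method under "within_method")."""

    def one_direction(dsa, dsb, queries):
        models = _rt_shift_models(dsa, dsb, cfg)
        cands = candidate_pairs(dsa, dsb, cfg, query_signals=queries)
        if cands.empty:
            return cands.assign(rt_delta=pd.Series(dtype=float), r=pd.Series(dtype=float))
        rt1 = dsa.meta["rt"]
        rt2 = dsb.meta["rt"]
        meth = dsa.meta["method"].map(cfg.canonical_method)
        deltas = np.full(len(cands), np.nan)
        for k, (sid1, sid2) in enumerate(zip(cands["signal1_id"], cands["signal2_id"])):
            key = meth[sid1] if cfg.partition == "within_method" else None
            if key not in models or pd.isna(rt1[sid1]) or pd.isna(rt2[sid2]):
                continue
            b0, b1 = models[key]
            deltas[k] = abs(rt2[sid2] - (b0 + b1 * rt1[sid1]))
        out = cands.assign(rt_delta=deltas).dropna(subset=["rt_delta"])
        out = out.assign(r=np.nan)
        return out

    fwd = one_direction(ds1, ds2, query_signals1)
    best_fwd = _select_best(fwd, by="rt_delta", ascending=True)
    if cfg.match_type == "multiple":
        pairs = best_fwd.assign(direction="1->2")
    elif cfg.match_type == "unique":
        pairs = _unique_filter(best_fwd, by="rt_delta", ascending=True).assign(direction="1->2")
    else:
        uniq_fwd = _unique_filter(best_fwd, by="rt_delta", ascending=True)
        rev = one_direction(ds2, ds1, query_signals2)
        uniq_rev = _unique_filter(
            _select_best(rev, by="rt_delta", ascending=True), by="rt_delta", ascending=True
        )
        rev_pairs = set(zip(uniq_rev["signal2_id"], uniq_rev["signal1_id"]))
        keep = [
            (s1, s2) in rev_pairs
            for s1, s2 in zip(uniq_fwd["signal1_id"], uniq_fwd["signal2_id"])
        ]
        pairs = uniq_fwd[keep].assign(direction="both")
    pairs = pairs.sort_values("signal1_id").reset_index(drop=True)
    cols = ["signal1_id", "signal2_id", "r", "d_used", "mz_resid", "rt_delta", "direction"]
    return MatchResult(pairs[cols], cfg)


# ---------------------------------------------------------------------------
# calibration with shared knowns


def default_setting_grid() -> list[MatchConfig]:
    """The calibration grid: adduct x correlation x match-type settings."""
    grid = []
    for adduct in ADDUCT_SETTINGS:
        for corr in CORRELATION_SETTINGS:
            for mtype in MATCH_TYPES:
                grid.append(
                    MatchConfig(
                        adduct_setting=adduct,
                        correlation_setting=corr,
                        match_type=mtype,
                    )
                )
    return grid


def calibrate_matching(
    ds1: ProfilingDataset,
    ds2: ProfilingDataset,
    setting_grid: list[MatchConfig] | None = None,
    matcher: str = "correlation",
    imputer: CrossImputer | None = None,
) -> pd.DataFrame:
    """Shared-known calibration of the matching parameters.

    Each known metabolite shared between the two datasets is treated as an
    unmatched signal and matched (leave-one-out models exclude the known
    from its own predictors).  Per setting combination the harness reports:
    match_count, correct_fraction (matched to itself), rsq08_fraction
    (matched to a dataset-2 signal whose observed squared correlation with
    the true known exceeds 0.8), and incorrect_rsq08_fraction.
    """
    shared = shared_known_names(ds1, ds2)
    if len(shared) < 2:
        raise ValidationError("need at least 2 shared knowns to calibrate")
    grid = setting_grid or default_setting_grid()
    if matcher == "correlation" and imputer is None:
        imputer = CrossImputer(ds1, ds2)
    q1 = [ds1.signal_of_known(k) for k in shared]
    q2 = [ds2.signal_of_known(k) for k in shared]
    obs2 = ds2.abundance.to_numpy(dtype=float)
    col2 = {c: j for j, c in enumerate(ds2.signal_ids)}
    Z2 = obs2 - obs2.mean(axis=0)
    n2 = np.sqrt((Z2**2).sum(axis=0))
    n2[n2 == 0] = np.nan
    rows = []
    for cfg in grid:
        if matcher == "correlation":
            res = match_signals(ds1, ds2, cfg, imputer=imputer,
                                query_signals1=q1, query_signals2=q2)
        elif matcher == "rt":
            res = match_by_rt(ds1, ds2, cfg, query_signals1=q1, query_signals2=q2)
        else:
            raise ValidationError(f"unknown matcher {matcher!r}")
        n_match = len(res.pairs)
        n_correct = 0
        n_rsq = 0
        for s1, s2 in zip(res.pairs["signal1_id"], res.pairs["signal2_id"]):
            name = ds1.meta.loc[s1, "known_name"]
            true2 = ds2.signal_of_known(name)
            if s2 == true2:
                n_correct += 1
                n_rsq += 1
                continue
            a, b = col2[s2], col2[true2]
            r = (Z2[:, a] @ Z2[:, b]) / (n2[a] * n2[b])
            if np.isfinite(r) and r * r > 0.8:
                n_rsq += 1
        denom = max(n_match, 1)
        rows.append(
            {
                "adduct_setting": cfg.adduct_setting,
                "correlation_setting": cfg.correlation_setting,
                "match_type": cfg.match_type,
                "partition": cfg.partition,
                "correlation_cutoff": cfg.correlation_cutoff,
                "match_count": n_match,
                "correct_fraction": n_correct / denom,
                "rsq08_fraction": n_rsq / denom,
                "incorrect_rsq08_fraction": (n_rsq - n_correct) / denom,
            }
        )
    return pd.DataFrame(rows)
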