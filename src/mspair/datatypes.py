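"""Core domain containers for untargeted LC-MS profiling data.

The universal in-memory object is :class:`ProfilingDataset`: a samples x
signals abundance matrix (pandas DataFrame, NaN = missing) together with
per-signal metadata (m/z, retention time, profiling method, ionization mode,
known-metabolite name when identified) and optional per-sample covariates.
Signal identity is carried by signal ids, never by column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "SignalMeta",
    "ProfilingDataset",
    "PathwayAnnotation",
    "AssocStats",
    "MetaboliteSet",
]

META_COLUMNS = ["signal_id", "mz", "rt", "method", "mode", "known_name"]
MODES = ("positive", "negative")


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


@dataclass(frozen=True)
class SignalMeta:
    """Metadata for one metabolite signal.

    ``known_name`` is the standardized metabolite name when the signal has
    been identified against reference standards; unknown signals carry only
    m/z / RT / method information.
    """

    signal_id: str
    mz: float | None = None
    rt: float | None = None
    method: str | None = None
    mode: str | None = None
    known_name: str | None = None

    def __post_init__(self) -> None:
        if self.mz is not None:
            if not np.isfinite(self.mz) or self.mz <= 0:
                raise ValidationError(
                    f"signal {self.signal_id!r}: mz must be positive, got {self.mz}"
                )
            if self.mode is None:
                raise ValidationError(
                    f"signal {self.signal_id!r}: ionization mode required when mz is present"
                )
        if self.mode is not None and self.mode not in MODES:
            raise ValidationError(
                f"signal {self.signal_id!r}: mode must be one of {MODES}, got {self.mode!r}"
            )

    @property
    def is_known(self) -> bool:
        return self.known_name is not None


class ProfilingDataset:
    """Samples x signals abundance matrix with signal metadata.

    Parameters
    ----------
    abundance
        DataFrame with sample ids as index and signal ids as columns;
        missing values are NaN.
    meta
        DataFrame indexed by signal id with columns ``mz``, ``rt``,
        ``method``, ``mode``, ``known_name`` (all optional per signal).
    covariates
        Optional per-sample DataFrame (e.g. age, sex, fasting time, BMI),
        indexed by sample id.
    """

    def __init__(
        self,
        abundance: pd.DataFrame,
        meta: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        name: str = "dataset",
    ):
        abundance = abundance.astype(float)
        if abundance.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if abundance.columns.has_duplicates:
            raise ValidationError("duplicate signal ids in abundance matrix")
        if meta.index.has_duplicates:
            raise ValidationError("duplicate signal ids in metadata")
        missing_meta = abundance.columns.difference(meta.index)
        if len(missing_meta):
            raise ValidationError(
                f"signals absent from metadata: {sorted(missing_meta)[:5]}"
            )
        meta = meta.reindex(abundance.columns)
        for col in ("mz", "rt", "method", "mode", "known_name"):
            if col not in meta.columns:
                meta[col] = np.nan
        # invariants checked through SignalMeta construction
        for sid, row in meta.iterrows():
            SignalMeta(
                signal_id=str(sid),
                mz=None if pd.isna(row["mz"]) else float(row["mz"]),
                rt=None if pd.isna(row["rt"]) else float(row["rt"]),
                method=None if pd.isna(row["method"]) else str(row["method"]),
                mode=None if pd.isna(row["mode"]) else str(row["mode"]),
                known_name=None if pd.isna(row["known_name"]) else str(row["known_name"]),
            )
        knowns = meta["known_name"].dropna()
        if knowns.duplicated().any():
            dup = sorted(knowns[knowns.duplicated()].unique())
            raise ValidationError(f"duplicate known metabolite names: {dup[:5]}")
        if covariates is not None:
            extra = abundance.index.difference(covariates.index)
            if len(extra):
                raise ValidationError(
                    f"samples absent from covariate table: {sorted(extra)[:5]}"
                )
            covariates = covariates.reindex(abundance.index)
        self.abundance = abundance
        self.meta = meta
        self.covariates = covariates
        self.name = name

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def signal_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_signals(self) -> int:
        return self.abundance.shape[1]

    @property
    def known_names(self) -> pd.Series:
        """Series mapping signal id -> known metabolite name (knowns only)."""
        return self.meta["known_name"].dropna()

    def signal_of_known(self, known_name: str) -> str:
        """Return the signal id carrying ``known_name``."""
        hits = self.meta.index[self.meta["known_name"] == known_name]
        if len(hits) != 1:
            raise KeyError(f"known metabolite {known_name!r} not present exactly once")
        return str(hits[0])

    def subset_signals(self, signal_ids) -> "ProfilingDataset":
        ids = list(signal_ids)
        return ProfilingDataset(
            self.abundance[ids], self.meta.loc[ids].copy(), self.covariates, self.name
        )

    def subset_samples(self, sample_ids) -> "ProfilingDataset":
        ids = list(sample_ids)
        cov = None if self.covariates is None else self.covariates.loc[ids]
        return ProfilingDataset(self.abundance.loc[ids], self.meta.copy(), cov, self.name)

    def copy_with(self, abundance: pd.DataFrame) -> "ProfilingDataset":
        return ProfilingDataset(abundance, self.meta.copy(), self.covariates, self.name)

    def equals(self, other: "ProfilingDataset", atol: float = 0.0) -> bool:
        if self.sample_ids != other.sample_ids or self.signal_ids != other.signal_ids:
            return False
        a, b = self.abundance.to_numpy(), other.abundance.to_numpy()
        same_nan = np.array_equal(np.isnan(a), np.isnan(b))
        close = np.allclose(np.nan_to_num(a), np.nan_to_num(b), atol=atol, rtol=0)
        meta_eq = self.meta.fillna("").astype(str).equals(other.meta.fillna("").astype(str))
        return bool(same_nan and close and meta_eq)

    def __repr__(self) -> str:  # pragma: no cover
        nk = int(self.meta["known_name"].notna().sum())
        return (
            f"ProfilingDataset({self.name!r}: {self.n_samples} samples x "
            f"{self.n_signals} signals, {nk} known)"
        )


@dataclass(frozen=True)
class PathwayAnnotation:
    """A curated metabolic pathway: a ``database:name`` label and its member
    metabolite names."""

    pathway_label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"pathway {self.pathway_label!r} has no members")


@dataclass(frozen=True)
class MetaboliteSet:
    """A unique combination of profiled known metabolites obtained by
    consolidating pathways whose profiled members coincide."""

    set_id: str
    members: frozenset[str]
    pathway_labels: tuple[str, ...]
    min_size_class: int = 2


class AssocStats:
    """Per-(variant, cohort, signal) association summary statistics.

    Thin wrapper around a DataFrame with columns ``variant_id``, ``cohort``,
    ``signal_id``, ``effect_allele``, ``beta``, ``se``, ``p``.
    """

    COLUMNS = ["variant_id", "cohort", "signal_id", "effect_allele", "beta", "se", "p"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"association table missing columns: {missing}")
        table = table[self.COLUMNS].copy()
        table[["beta", "se", "p"]] = table[["beta", "se", "p"]].astype(float)
        bad = table.index[~(table["se"] > 0)]
        if len(bad):
            raise ValidationError(f"non-positive standard error at rows {list(bad[:5])}")
        bad_p = table.index[(table["p"] <= 0) | (table["p"] > 1)]
        if len(bad_p):
            raise ValidationError(f"p-values outside (0, 1] at rows {list(bad_p[:5])}")
        key = table[["variant_id", "cohort", "signal_id"]]
        if key.duplicated().any():
            raise ValidationError("duplicate (variant, cohort, signal) records")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def for_cohort(self, cohort: str) -> pd.DataFrame:
        return self.table[self.table["cohort"] == cohort]

    def for_signal(self, cohort: str, signal_id: str) -> pd.DataFrame:
        t = self.table
        return t[(t["cohort"] == cohort) & (t["signal_id"] == signal_id)]

    def equals(self, other: "AssocStats") -> bool:
        a, b = self.table, other.table
        if a.shape != b.shape:
            return False
        obj = ["variant_id", "cohort", "signal_id", "effect_allele"]
        return bool(
            a[obj].equals(b[obj])
            and np.allclose(a[["beta", "se", "p"]], b[["beta", "se", "p"]], rtol=1e-9)
        )
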