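"""TSV readers and writers for all domain objects.

All tabular I/O is tab-separated text.  Missing values are encoded "NA";
floats are written with 10 significant digits so read(write(x)) == x up to
float formatting.  Signal ids, not column order, define identity.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AssocStats,
    FormatError,
    PathwayAnnotation,
    ProfilingDataset,
    ValidationError,
)

logger = logging.getLogger("mspair")

NA = "NA"
FLOAT_FMT = "%.10g"


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False, **kw)
    except pd.errors.ParserError as e:  # ragged rows etc.
        raise FormatError(f"{path}: {e}") from e


def read_profiling_dataset(
    abundance_path, meta_path, covariate_path=None, name: str | None = None
) -> ProfilingDataset:
    """Read a dataset from an abundance TSV (first column = sample id, header
    = signal ids), a signal-metadata TSV, and an optional covariate TSV."""
    abundance = _read_tsv(abundance_path, index_col=0)
    if abundance.columns.size == 0:
        raise FormatError(f"{abundance_path}: no signal columns")
    meta = _read_tsv(meta_path)
    if "signal_id" not in meta.columns:
        raise FormatError(f"{meta_path}: missing 'signal_id' column")
    if meta["signal_id"].duplicated().any():
        raise ValidationError(f"{meta_path}: duplicate signal ids")
    meta = meta.set_index("signal_id")
    covariates = None
    if covariate_path is not None:
        covariates = _read_tsv(covariate_path, index_col=0)
    ds = ProfilingDataset(
        abundance, meta, covariates, name=name or Path(str(abundance_path)).stem
    )
    logger.info(
        "read dataset %s: %d samples x %d signals", ds.name, ds.n_samples, ds.n_signals
    )
    return ds


def write_profiling_dataset(ds: ProfilingDataset, abundance_path, meta_path, covariate_path=None):
    ds.abundance.to_csv(abundance_path, sep="\t", na_rep=NA, float_format=FLOAT_FMT)
    meta = ds.meta.copy()
    meta.index.name = "signal_id"
    meta.to_csv(meta_path, sep="\t", na_rep=NA, float_format=FLOAT_FMT)
    if covariate_path is not None and ds.covariates is not None:
        ds.covariates.to_csv(covariate_path, sep="\t", na_rep=NA, float_format=FLOAT_FMT)


def read_pathway_annotations(path) -> list[PathwayAnnotation]:
    """Read pathways from a TSV with columns ``pathway_label`` and a
    pipe-separated (or tab-continued) member list.

    Rows with an empty member list are rejected with a warning; duplicate
    labels are a validation error; duplicate members within a row are
    de-duplicated silently.
    """
    out: list[PathwayAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("pathway_label"):
            raise FormatError(f"{path}: expected header starting with 'pathway_label'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            label = parts[0]
            members = {
                m.strip()
                for field in parts[1:]
                for m in field.split("|")
                if m.strip()
            }
            if label in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway label {label!r}")
            if not members:
                logger.warning("%s:%d: pathway %r has no members, skipped", path, lineno, label)
                continue
            seen.add(label)
            out.append(PathwayAnnotation(label, frozenset(members)))
    logger.info("read %d pathways from %s", len(out), path)
    return out


def write_pathway_annotations(pathways, path):
    with open(path, "w") as fh:
        fh.write("pathway_label\tmembers\n")
        for p in pathways:
            fh.write(f"{p.pathway_label}\t{'|'.join(sorted(p.members))}\n")


def read_association_table(path) -> AssocStats:
    """Read per-(variant, cohort, signal) summary statistics."""
    table = _read_tsv(path)
    missing = [c for c in AssocStats.COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    try:
        stats = AssocStats(table)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e
    logger.info("read %d association records from %s", len(stats), path)
    return stats


def write_association_table(stats: AssocStats, path):
    stats.table.to_csv(path, sep="\t", index=False, na_rep=NA, float_format=FLOAT_FMT)


def read_match_result(path) -> pd.DataFrame:
    t = _read_tsv(path)
    need = {"signal1_id", "signal2_id"}
    if not need.issubset(t.columns):
        raise FormatError(f"{path}: missing columns {sorted(need - set(t.columns))}")
    return t


def write_match_result(pairs: pd.DataFrame, path):
    pairs.to_csv(path, sep="\t", index=False, na_rep=NA, float_format=FLOAT_FMT)
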