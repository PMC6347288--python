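"""QC and transformation of one profiling dataset.

Builds a small raw abundance matrix with missing values and outliers, runs
the pipeline (outlier masking -> missingness filter -> chained imputation ->
covariate adjustment -> rank-based inverse normal transform) and prints what
each stage did.
"""

import numpy as np
import pandas as pd

from mspair import PreprocessConfig, ProfilingDataset, run_pipeline

rng = np.random.default_rng(0)
n = 60
signals = {f"sig{j:02d}": rng.normal(10, 2, size=n) for j in range(12)}
signals["sig00"][5] = 60.0            # gross outlier
for sid in list(signals)[:6]:
    miss = rng.choice(n, size=8, replace=False)
    signals[sid][miss] = np.nan       # moderate missingness
signals["sig11"][rng.choice(n, size=45, replace=False)] = np.nan  # mostly missing

ab = pd.DataFrame(signals, index=[f"s{i:02d}" for i in range(n)])
meta = pd.DataFrame(index=ab.columns)
meta.index.name = "signal_id"
cov = pd.DataFrame({"age": rng.uniform(20, 70, n), "sex": rng.integers(0, 2, n)},
                   index=ab.index, dtype=float)
ds = ProfilingDataset(ab, meta, cov, name="demo")

cfg = PreprocessConfig(signal_missing_max=0.5, sample_missing_max=0.5)
out, report = run_pipeline(ds, cfg, covariate_names=["age", "sex"])

print(f"input: {ds.n_samples} samples x {ds.n_signals} signals")
print(f"dropped signals (> 50% missing): {report['dropped_signals']}")
print(f"dropped samples: {report['dropped_samples']}")
print(f"output: {out.n_samples} samples x {out.n_signals} signals, "
      f"{int(out.abundance.isna().sum().sum())} missing values remain")
col = out.abundance["sig00"]
print(f"sig00 after transform: mean = {col.mean():.3f}, sd = {col.std():.3f} "
      "(abundance z-scores: each signal is rank-normalized)")
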