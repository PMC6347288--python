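import numpy as np
import pandas as pd
import pytest

from mspair import ProfilingDataset, SimConfig, simulate_cohort_pair


def make_dataset(values, signal_meta, sample_ids=None, covariates=None, name="toy"):
    """Build a small ProfilingDataset from a dict signal_id -> values and a
    dict signal_id -> meta fields."""
    ab = pd.DataFrame(values)
    if sample_ids is not None:
        ab.index = sample_ids
    else:
        ab.index = [f"s{i}" for i in range(len(ab))]
    meta = pd.DataFrame(signal_meta.values(), index=list(signal_meta.keys()))
    meta.index.name = "signal_id"
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates, index=ab.index)
    return ProfilingDataset(ab, meta, cov, name=name)


@pytest.fixture(scope="session")
def sim_pair_small():
    """A small but realistic cohort pair: 150 samples, 60 shared knowns."""
    cfg = SimConfig(
        n_samples=150, n_latent=80, n_known=60, n_unknown=40, n_factors=20,
        cohort_similarity=0.6, seed=11,
    )
    return (*simulate_cohort_pair(cfg), cfg)


@pytest.fixture(scope="session")
def sim_pair_pathways():
    """A single-cohort regime with many knowns for pathway tests."""
    cfg = SimConfig(
        n_samples=200, n_latent=180, n_known=150, n_unknown=40, n_factors=25,
        cohort_similarity=0.6, seed=21,
    )
    ds1, ds2, truth = simulate_cohort_pair(cfg)
    return ds1, truth, cfg
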