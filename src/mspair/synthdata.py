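"""Seeded generators for cohort pairs, pathway structures and association
summary statistics.

The generator emulates the statistical regime the matching and pathway
methods assume: two cohorts profile the same latent metabolites through a
shared factor model, a subset of metabolites is identified by name in both
("shared knowns"), each metabolite emits one or more adduct signals whose
m/z is the neutral mass plus the adduct shift, and cohort-to-cohort
similarity of the metabolite correlation structure is tuned to a target
r-squared of the correlation-of-correlations.  Truth tables map every
signal back to its latent metabolite so downstream matches and validation
statistics can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AssocStats, PathwayAnnotation, ProfilingDataset, ValidationError
from .matching import AdductTable

logger = logging.getLogger("mspair")

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_cohort_pair",
    "simulate_pathways",
    "simulate_association_stats",
]


@dataclass
class SimConfig:
    """Study conditions for the simulated cohort pair.

    Defaults follow the regime the methods are designed for: ~300 samples
    per dataset, ~200 shared known metabolites, and moderate similarity of
    the metabolite correlation structure (r^2 ~ 0.6) between cohorts.
    ``collision_fraction`` controls how many known metabolites receive an
    m/z-colliding decoy signal (a distinct metabolite within the matching
    tolerance), which is what makes matching non-trivial.
    """

    n_samples: int = 300
    n_latent: int = 260
    n_factors: int = 40
    factor_loading_sd: float = 1.0
    primary_share: float = 0.8
    communality: float = 0.75
    noise_sd: float = 0.25
    n_known: int = 200
    n_unknown: int = 120
    adduct_profile: tuple[str, ...] = ("[M+H]+", "[M+Na]+")
    collision_fraction: float = 0.5
    cohort_similarity: float = 0.6
    rt_shift: tuple[float, float] = (0.5, 1.05)
    rt_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_known > self.n_latent:
            raise ValidationError("n_known must not exceed n_latent")
        if not 0 < self.cohort_similarity <= 1:
            raise ValidationError("cohort_similarity must be in (0, 1]")
        if self.n_unknown < self.n_latent - self.n_known:
            raise ValidationError(
                "n_unknown must cover the non-known latent metabolites "
                f"(>= {self.n_latent - self.n_known})"
            )


@dataclass
class SimTruth:
    """Ground truth for a simulated cohort pair.

    ``signals`` has one row per (dataset, signal): the latent metabolite it
    measures, its adduct and whether it is a named known.  ``loadings`` is
    the shared factor-loading matrix (factors x metabolites) and
    ``dominant_factor`` the argmax-|loading| factor per metabolite.
    """

    signals: pd.DataFrame
    metabolite_names: list[str]
    loadings: np.ndarray
    dominant_factor: np.ndarray
    realized_similarity: float

    def pair_table(self) -> pd.DataFrame:
        """True cross-dataset partner for every dataset-1 signal (the
        dataset-2 signal measuring the same latent metabolite and adduct)."""
        s = self.signals
        d1 = s[s["dataset"] == 1].set_index(["latent", "adduct"])["signal_id"]
        d2 = s[s["dataset"] == 2].set_index(["latent", "adduct"])["signal_id"]
        joined = pd.DataFrame({"signal1_id": d1, "signal2_id": d2}).dropna()
        return joined.reset_index(drop=True)


def _draw_masses(rng: np.random.Generator, n: int, lo=80.0, hi=900.0, spacing=0.02):
    """Neutral monoisotopic masses with a minimum pairwise spacing."""
    for _ in range(200):
        m = np.sort(rng.uniform(lo, hi, size=n))
        if np.all(np.diff(m) >= spacing):
            return m
    # enforce spacing deterministically on the last draw
    m = np.sort(rng.uniform(lo, hi, size=n))
    for i in range(1, n):
        m[i] = max(m[i], m[i - 1] + spacing)
    return m


def _unit_columns(L: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(L, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    return L / norms


def _corr_of_corr(X1: np.ndarray, X2: np.ndarray) -> float:
    """r^2 of the off-diagonal pairwise correlations between two matrices'
    columns (the similarity measure for metabolite correlation structure)."""
    C1 = np.corrcoef(X1, rowvar=False)
    C2 = np.corrcoef(X2, rowvar=False)
    iu = np.triu_indices_from(C1, k=1)
    r = np.corrcoef(C1[iu], C2[iu])[0, 1]
    return float(r**2)


def simulate_cohort_pair(cfg: SimConfig):
    """Simulate two cohorts profiling the same latent metabolites.

    Returns (ds1, ds2, truth).  Cohort 2's factor loadings interpolate
    between cohort 1's and an independent draw; the mixing weight is
    calibrated by bisection so the realized correlation-of-correlations of
    the *observed* known signals (measurement noise included) matches
    ``cfg.cohort_similarity``.  A target of exactly 1.0 means "identical
    loadings": sampling noise keeps the realized value below 1, so no
    calibration is attempted.
    """
    rng = np.random.default_rng(cfg.seed)
    k, p = cfg.n_factors, cfg.n_latent

    def module_loadings(primary_assignment):
        # each metabolite: one strong primary factor plus a dense background
        dense = _unit_columns(rng.normal(0, cfg.factor_loading_sd, size=(k, p)))
        L = np.sqrt(1 - cfg.primary_share) * dense
        L[primary_assignment, np.arange(p)] += np.sqrt(cfg.primary_share)
        return _unit_columns(L)

    primary = rng.integers(0, k, size=p)
    L_shared = module_loadings(primary)
    L_indep = module_loadings(rng.integers(0, k, size=p))
    F1 = rng.standard_normal((cfg.n_samples, k))
    F2 = rng.standard_normal((cfg.n_samples, k))
    U1 = rng.standard_normal((cfg.n_samples, p))
    U2 = rng.standard_normal((cfg.n_samples, p))
    h = np.sqrt(cfg.communality)
    u = np.sqrt(1 - cfg.communality)

    def latents(Fc, Uc, L):
        return h * (Fc @ L) + u * Uc

    X1 = latents(F1, U1, L_shared)
    kn = slice(0, cfg.n_known)
    # measurement noise of the known signals, shared between the similarity
    # calibration and the emitted signals so the realized value is exact
    E1k = rng.standard_normal((cfg.n_samples, cfg.n_known))
    E2k = rng.standard_normal((cfg.n_samples, cfg.n_known))

    def mix(alpha: float) -> np.ndarray:
        return _unit_columns(alpha * L_shared + np.sqrt(max(1 - alpha**2, 0.0)) * L_indep)

    def realized(alpha: float) -> float:
        X2 = latents(F2, U2, mix(alpha))
        return _corr_of_corr(
            X1[:, kn] + cfg.noise_sd * E1k, X2[:, kn] + cfg.noise_sd * E2k
        )

    # sampling noise caps the realized similarity; a target within this
    # slack of the cap uses the closest attainable mixing instead of failing
    slack = 0.02
    if cfg.cohort_similarity >= 1.0:
        alpha = 1.0
    else:
        lo, hi = 0.0, 1.0
        r_hi = realized(1.0)
        if r_hi + slack < cfg.cohort_similarity:
            raise ValidationError(
                f"similarity target {cfg.cohort_similarity} infeasible "
                f"(max realized {r_hi:.3f})"
            )
        alpha = 1.0
        if r_hi >= cfg.cohort_similarity:
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                r_mid = realized(mid)
                if abs(r_mid - cfg.cohort_similarity) < 0.005:
                    alpha = mid
                    break
                if r_mid < cfg.cohort_similarity:
                    lo = mid
                else:
                    hi = mid
                alpha = 0.5 * (lo + hi)
    L2 = mix(alpha)
    X2 = latents(F2, U2, L2)
    realized_sim = realized(alpha)

    # --- signal layout (shared across cohorts) --------------------------
    masses = _draw_masses(rng, p)
    names = [f"met_{i:04d}" for i in range(p)]
    table = AdductTable()
    shift = {a.name: a.shift for a in table.entries}
    layout = []  # (latent, adduct, mz, is_known)
    for i in range(p):
        layout.append((i, cfg.adduct_profile[0], masses[i] + shift[cfg.adduct_profile[0]],
                       i < cfg.n_known))
    n_extra = cfg.n_unknown - (p - cfg.n_known)
    extra_adducts = cfg.adduct_profile[1:] or cfg.adduct_profile[:1]
    for u_i in range(n_extra):
        lat = int(rng.integers(0, p))
        ad = extra_adducts[u_i % len(extra_adducts)]
        layout.append((lat, ad, masses[lat] + shift[ad], False))
    # m/z-colliding decoys next to known signals
    n_coll = int(round(cfg.collision_fraction * cfg.n_known))
    coll_known = rng.choice(cfg.n_known, size=n_coll, replace=False)
    for ki in coll_known:
        lat = int(rng.integers(cfg.n_known, p)) if p > cfg.n_known else int(rng.integers(0, p))
        offset = rng.uniform(-0.004, 0.004)
        layout.append((lat, f"decoy@{names[ki]}", masses[ki] + shift[cfg.adduct_profile[0]] + offset,
                       False))

    rt1 = rng.uniform(1.0, 15.0, size=p)
    a0, a1 = cfg.rt_shift

    def build(dataset: int, X: np.ndarray, Ek: np.ndarray) -> tuple[ProfilingDataset, list[dict]]:
        rows = []
        data = {}
        meta_rows = {}
        scale = np.sqrt(1 + cfg.noise_sd**2)
        for j, (lat, ad, mz, is_known) in enumerate(layout):
            if is_known:
                sid = f"d{dataset}_{names[lat]}"
                known = names[lat]
                eps = Ek[:, lat]
            else:
                sid = f"d{dataset}_u{j:04d}"
                known = None
                eps = rng.standard_normal(cfg.n_samples)
            vals = (X[:, lat] + cfg.noise_sd * eps) / scale
            data[sid] = vals
            rt = rt1[lat] if dataset == 1 else a0 + a1 * rt1[lat] + rng.normal(0, cfg.rt_noise_sd)
            meta_rows[sid] = {
                "mz": mz, "rt": rt, "method": "HILIC-pos", "mode": "positive",
                "known_name": known,
            }
            rows.append({
                "dataset": dataset, "signal_id": sid, "latent": lat,
                "metabolite": names[lat], "adduct": ad, "is_known": is_known,
            })
        samples = [f"c{dataset}_s{i:04d}" for i in range(cfg.n_samples)]
        ab = pd.DataFrame(data, index=samples)
        meta = pd.DataFrame.from_dict(meta_rows, orient="index")
        meta.index.name = "signal_id"
        return ProfilingDataset(ab, meta, name=f"cohort{dataset}"), rows

    ds1, rows1 = build(1, X1, E1k)
    ds2, rows2 = build(2, X2, E2k)
    truth = SimTruth(
        signals=pd.DataFrame(rows1 + rows2),
        metabolite_names=names,
        loadings=L_shared,
        dominant_factor=primary,
        realized_similarity=realized_sim,
    )
    logger.info(
        "simulated cohort pair: %d+%d signals, realized similarity r^2 = %.3f",
        ds1.n_signals, ds2.n_signals, realized_sim,
    )
    return ds1, ds2, truth


def simulate_pathways(
    truth: SimTruth,
    n_sets: int = 30,
    set_size_range: tuple[int, int] = (5, 15),
    coherence: float = 1.0,
    seed: int = 0,
) -> list[PathwayAnnotation]:
    """Planted pathway annotations over the simulated known metabolites.

    With probability ``coherence`` a set draws its members from within a
    single factor module (factors are used without replacement while
    available and the set size is capped by the module size, so a coherent
    set never straddles modules); otherwise members are uniform draws.
    """
    if not 0 <= coherence <= 1:
        raise ValidationError("coherence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    known_idx = np.array(
        sorted(
            truth.signals.loc[
                (truth.signals["dataset"] == 1) & truth.signals["is_known"], "latent"
            ].unique()
        )
    )
    names = truth.metabolite_names
    out = []
    lo, hi = set_size_range
    n_factors = truth.loadings.shape[0]
    modules = {
        f: known_idx[truth.dominant_factor[known_idx] == f] for f in range(n_factors)
    }
    factor_pool = [f for f in rng.permutation(n_factors) if len(modules[f]) >= 2]
    for s_i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(known_idx))
        if rng.random() < coherence:
            if factor_pool:
                f = int(factor_pool.pop())
            else:  # more coherent sets than usable modules: reuse at random
                usable = [f for f in range(n_factors) if len(modules[f]) >= 2]
                f = int(rng.choice(usable))
            members_idx = rng.choice(
                modules[f], size=min(size, len(modules[f])), replace=False
            )
        else:
            members_idx = rng.choice(known_idx, size=size, replace=False)
        out.append(
            PathwayAnnotation(
                pathway_label=f"SIM:set_{s_i:03d}",
                members=frozenset(names[i] for i in members_idx),
            )
        )
    return out


def simulate_association_stats(
    truth: SimTruth,
    n_variants: int = 30,
    effect_sd: float = 0.2,
    shared_effect_fraction: float = 1.0,
    n_per_cohort: int = 500,
    seed: int = 0,
) -> tuple[AssocStats, AssocStats]:
    """Variant-signal summary statistics for both cohorts.

    Each (variant, metabolite) pair carries a latent effect drawn
    N(0, effect_sd^2); with probability ``shared_effect_fraction`` the same
    effect acts in both cohorts, otherwise the cohorts get independent
    draws.  Observed betas add sampling noise with se = 1/sqrt(n); effects
    propagate to every signal of the metabolite.
    """
    rng = np.random.default_rng(seed)
    p = len(truth.metabolite_names)
    se = 1.0 / np.sqrt(n_per_cohort)
    b1 = rng.normal(0, effect_sd, size=(n_variants, p))
    b_indep = rng.normal(0, effect_sd, size=(n_variants, p))
    shared = rng.random((n_variants, p)) < shared_effect_fraction
    b2 = np.where(shared, b1, b_indep)
    variants = [f"var_{v:04d}" for v in range(n_variants)]

    def cohort_table(dataset: int, b_true: np.ndarray) -> AssocStats:
        sig = truth.signals[truth.signals["dataset"] == dataset]
        obs = b_true + rng.normal(0, se, size=b_true.shape)
        from scipy import stats as _st

        rows = []
        for _, row in sig.iterrows():
            lat = int(row["latent"])
            for v in range(n_variants):
                beta = obs[v, lat]
                z = beta / se
                rows.append(
                    (variants[v], f"cohort{dataset}", row["signal_id"], "A",
                     beta, se, max(2 * _st.norm.sf(abs(z)), 1e-300))
                )
        return AssocStats(
            pd.DataFrame(rows, columns=AssocStats.COLUMNS)
        )

    return cohort_table(1, b1), cohort_table(2, b2)
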