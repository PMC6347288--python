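import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mspair import (
    AdductTable,
    CrossImputer,
    MatchConfig,
    ValidationError,
    adduct_shift_set,
    calibrate_matching,
    candidate_pairs,
    fit_imputation_model,
    impute_across,
    match_by_rt,
    match_signals,
    mz_agree,
    pair_correlation,
)
from mspair.matching import ELECTRON_MASS, NA_MASS, NH4_MASS, PROTON_MASS
from conftest import make_dataset


class TestAdductShiftSet:
    def test_same_mode_no_adduct_is_zero(self):
        assert adduct_shift_set("positive", "positive", "no_adduct").tolist() == [0.0]

    def test_pos_neg_no_adduct_is_two_protons(self):
        (d,) = adduct_shift_set("positive", "negative", "no_adduct")
        assert d == pytest.approx(2 * PROTON_MASS, abs=1e-9)
        assert d == pytest.approx(2.014553, abs=1e-5)

    def test_adduct_set_matches_brute_force_enumeration(self):
        table = AdductTable()
        shifts = {a.name: a.shift for a in table.entries}
        pos = ["M+", "[M+H]+", "[M+NH4]+", "[M+Na]+"]
        expected = sorted({round(shifts[a] - shifts[b], 9) for a in pos for b in pos})
        got = adduct_shift_set("positive", "positive", "adduct")
        assert np.allclose(got, expected)
        assert any(abs(d - (NA_MASS - PROTON_MASS)) < 1e-9 for d in got)  # Na-H
        assert any(abs(d - 21.98194) < 1e-4 for d in got)

    def test_unknown_mode_errors(self):
        with pytest.raises(ValidationError):
            adduct_shift_set("positive", "radical", "no_adduct")


class TestMzAgree:
    CFG = MatchConfig()

    def test_within_tolerance(self):
        ok, d = mz_agree(200.0000, "positive", 200.0049, "positive", "no_adduct", self.CFG)
        assert ok and d == 0.0

    def test_boundary_exclusion(self):
        ok, d = mz_agree(200.0000, "positive", 200.0051, "positive", "no_adduct", self.CFG)
        assert not ok and d is None

    def test_sodium_hydrogen_shift(self):
        ok, d = mz_agree(121.98194, "positive", 100.0, "positive", "adduct", self.CFG)
        assert ok
        assert d == pytest.approx(NA_MASS - PROTON_MASS, abs=1e-9)

    def test_missing_mz_returns_false(self):
        assert mz_agree(None, "positive", 100.0, "positive", "adduct", self.CFG) == (False, None)

    @given(
        st.floats(80, 900), st.floats(-0.02, 0.02),
        st.sampled_from(["positive", "negative"]), st.sampled_from(["positive", "negative"]),
        st.sampled_from(["no_adduct", "adduct"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry_under_swap(self, mz1, delta, mode1, mode2, setting):
        mz2 = mz1 + delta
        ok12, d12 = mz_agree(mz1, mode1, mz2, mode2, setting, self.CFG)
        ok21, d21 = mz_agree(mz2, mode2, mz1, mode1, setting, self.CFG)
        assert ok12 == ok21
        if ok12:
            assert d12 == pytest.approx(-d21, abs=1e-12)

    @given(st.floats(80, 900), st.floats(-25, 25))
    @settings(max_examples=200, deadline=None)
    def test_against_naive_enumeration(self, mz1, delta):
        mz2 = mz1 + delta
        ds = adduct_shift_set("positive", "positive", "adduct")
        expect = any(abs((mz1 - mz2) - d) <= 0.005 for d in ds)
        ok, _ = mz_agree(mz1, "positive", mz2, "positive", "adduct", self.CFG)
        assert ok == expect


def _pair_datasets(seed=0, n_samples=40, n_extra1=4, n_extra2=5, across_methods=False):
    """Two tiny complete datasets with 4 shared knowns, m/z near-collisions
    and (optionally) mixed profiling methods."""
    rng = np.random.default_rng(seed)
    knowns = ["ala", "gly", "ser", "thr"]
    base_mass = {k: 90.0 + 40 * i for i, k in enumerate(knowns)}
    lat = rng.standard_normal((n_samples, 10))

    def build(tag, n_extra):
        vals, meta = {}, {}
        for i, k in enumerate(knowns):
            sid = f"{tag}_{k}"
            vals[sid] = lat[:, i] + 0.2 * rng.standard_normal(n_samples)
            meta[sid] = {
                "mz": base_mass[k] + PROTON_MASS, "rt": 1.0 + i,
                "method": "HILIC-pos", "mode": "positive", "known_name": k,
            }
        for j in range(n_extra):
            sid = f"{tag}_u{j}"
            src = rng.integers(0, 10)
            vals[sid] = lat[:, src] + 0.3 * rng.standard_normal(n_samples)
            near = knowns[j % len(knowns)]
            method = "C18-neg" if (across_methods and j % 2) else "HILIC-pos"
            meta[sid] = {
                "mz": base_mass[near] + PROTON_MASS + rng.uniform(-0.004, 0.004),
                "rt": rng.uniform(1, 5),
                "method": method, "mode": "positive", "known_name": None,
            }
        return make_dataset(vals, meta, name=tag)

    return build("d1", n_extra1), build("d2", n_extra2)


class TestCandidatePairs:
    def test_no_partner_absent_from_output(self):
        ds1, ds2 = _pair_datasets()
        # give one ds1 signal an m/z far from everything
        ds1.meta.loc["d1_u0", "mz"] = 500.123456
        cands = candidate_pairs(ds1, ds2, MatchConfig(adduct_setting="no_adduct"))
        assert "d1_u0" not in set(cands["signal1_id"])

    def test_combined_suppresses_adduct_when_no_adduct_hits(self):
        ds1, ds2 = _pair_datasets()
        cfg_c = MatchConfig(adduct_setting="combined")
        cfg_n = MatchConfig(adduct_setting="no_adduct")
        cands_c = candidate_pairs(ds1, ds2, cfg_c)
        cands_n = candidate_pairs(ds1, ds2, cfg_n)
        for sid in set(cands_n["signal1_id"]):
            got = set(cands_c[cands_c["signal1_id"] == sid]["signal2_id"])
            expect = set(cands_n[cands_n["signal1_id"] == sid]["signal2_id"])
            assert got == expect

    def test_combined_falls_back_to_adducts(self):
        ds1, ds2 = _pair_datasets()
        # move one ds1 signal so only a Na-for-H swap can match it
        ds1.meta.loc["d1_u1", "mz"] = ds2.meta.loc["d2_ala", "mz"] + (NA_MASS - PROTON_MASS)
        cands = candidate_pairs(ds1, ds2, MatchConfig(adduct_setting="combined"))
        hit = cands[cands["signal1_id"] == "d1_u1"]
        assert "d2_ala" in set(hit["signal2_id"])

    def test_across_method_includes_cross_method_pair(self):
        ds1, ds2 = _pair_datasets(across_methods=True)
        within = candidate_pairs(ds1, ds2, MatchConfig(partition="within_method"))
        across = candidate_pairs(ds1, ds2, MatchConfig(partition="across_method"))
        meth1 = ds1.meta["method"]
        meth2 = ds2.meta["method"]
        cross = [
            (a, b) for a, b in zip(across["signal1_id"], across["signal2_id"])
            if meth1[a] != meth2[b]
        ]
        assert cross  # across-method pairs exist
        assert not [
            (a, b) for a, b in zip(within["signal1_id"], within["signal2_id"])
            if meth1[a] != meth2[b]
        ]


class TestImputation:
    def test_exact_predictor_recovered(self):
        ds1, ds2 = _pair_datasets(seed=3)
        # make a ds1 unknown equal to the known "gly" exactly
        ds1.abundance["d1_u0"] = ds1.abundance["d1_gly"]
        model = fit_imputation_model(ds1, "d1_u0", ["ala", "gly", "ser", "thr"])
        coefs = dict(zip(model.predictor_names, model.coef))
        assert coefs["gly"] == pytest.approx(1.0, abs=1e-8)
        for k in ("ala", "ser", "thr"):
            assert coefs[k] == pytest.approx(0.0, abs=1e-6)

    def test_known_target_excluded_from_predictors(self):
        ds1, _ = _pair_datasets()
        model = fit_imputation_model(ds1, "d1_gly", ["ala", "gly", "ser", "thr"])
        assert "gly" not in model.predictor_names

    def test_constant_target(self):
        ds1, _ = _pair_datasets()
        ds1.abundance["d1_u0"] = 2.5
        model = fit_imputation_model(ds1, "d1_u0", ["ala", "gly", "ser", "thr"])
        assert np.allclose(model.coef, 0.0, atol=1e-8)
        assert model.intercept == pytest.approx(2.5)

    def test_in_sample_prediction_equals_fitted(self):
        ds1, _ = _pair_datasets(seed=4)
        shared = ["ala", "gly", "ser", "thr"]
        model = fit_imputation_model(ds1, "d1_u1", shared)
        X = np.column_stack(
            [ds1.abundance[ds1.signal_of_known(k)] for k in model.predictor_names]
        )
        fitted = model.intercept + X @ model.coef
        assert np.allclose(impute_across(ds1, ds1, model), fitted)

    def test_prediction_is_matrix_product(self):
        ds1, ds2 = _pair_datasets(seed=5)
        model = fit_imputation_model(ds1, "d1_u2", ["ala", "gly", "ser", "thr"])
        X2 = np.column_stack(
            [ds2.abundance[ds2.signal_of_known(k)] for k in model.predictor_names]
        )
        assert np.allclose(
            impute_across(ds1, ds2, model), model.intercept + X2 @ model.coef
        )

    def test_cross_imputer_agrees_with_per_signal_models(self):
        ds1, ds2 = _pair_datasets(seed=6)
        imp = CrossImputer(ds1, ds2)
        shared = ["ala", "gly", "ser", "thr"]
        for sid in ("d1_u0", "d1_gly"):
            model = fit_imputation_model(ds1, sid, shared)
            assert np.allclose(
                imp.imputed_1_in_2[sid], impute_across(ds1, ds2, model), atol=1e-8
            )


class TestPairCorrelation:
    def test_identity_and_antipodal(self):
        ds1, ds2 = _pair_datasets(seed=7)
        imp = CrossImputer(ds1, ds2)
        imp.imputed_2_in_1["d2_u0"] = ds1.abundance["d1_u0"]
        assert pair_correlation("d1_u0", "d2_u0", "dataset1", imp) == pytest.approx(1.0)
        imp.imputed_2_in_1["d2_u0"] = -ds1.abundance["d1_u0"]
        assert pair_correlation("d1_u0", "d2_u0", "dataset1", imp) == pytest.approx(-1.0)

    @pytest.mark.parametrize("setting", ["dataset1", "dataset2", "all"])
    def test_against_direct_pearson(self, setting):
        ds1, ds2 = _pair_datasets(seed=8, n_samples=6)
        imp = CrossImputer(ds1, ds2)
        r = pair_correlation("d1_u1", "d2_u2", setting, imp)
        obs1 = ds1.abundance["d1_u1"].to_numpy()
        obs2 = ds2.abundance["d2_u2"].to_numpy()
        imp1 = imp.imputed_1_in_2["d1_u1"].to_numpy()
        imp2 = imp.imputed_2_in_1["d2_u2"].to_numpy()
        if setting == "dataset1":
            ref = stats.pearsonr(obs1, imp2).statistic
        elif setting == "dataset2":
            ref = stats.pearsonr(imp1, obs2).statistic
        else:
            ref = stats.pearsonr(
                np.concatenate([obs1, imp1]), np.concatenate([imp2, obs2])
            ).statistic
        assert r == pytest.approx(ref, abs=1e-10)


def brute_force_match(ds1, ds2, cfg, imputer):
    """Independent re-implementation of candidate generation and match
    selection with plain loops and scipy Pearson correlations."""

    def canon(m):
        return dict(cfg.method_aliases).get(m, m)

    def corr(s1, s2, flip):
        dsq, dsc = (ds2, ds1) if flip else (ds1, ds2)
        impq = imputer.imputed_2_in_1 if flip else imputer.imputed_1_in_2
        impc = imputer.imputed_1_in_2 if flip else imputer.imputed_2_in_1
        if cfg.correlation_setting == "dataset1":
            return stats.pearsonr(dsq.abundance[s1], impc[s2]).statistic
        if cfg.correlation_setting == "dataset2":
            return stats.pearsonr(impq[s1], dsc.abundance[s2]).statistic
        return stats.pearsonr(
            np.concatenate([dsq.abundance[s1], impq[s1]]),
            np.concatenate([impc[s2], dsc.abundance[s2]]),
        ).statistic

    def cands_for(dsa, dsb, s1):
        m1 = dsa.meta.loc[s1]
        if pd.isna(m1["mz"]):
            return []
        out = {}
        for setting in (["no_adduct"] if cfg.adduct_setting == "no_adduct"
                        else ["adduct"] if cfg.adduct_setting == "adduct"
                        else ["no_adduct", "adduct"]):
            for s2 in dsb.signal_ids:
                m2 = dsb.meta.loc[s2]
                if pd.isna(m2["mz"]):
                    continue
                if cfg.partition == "within_method" and canon(m1["method"]) != canon(m2["method"]):
                    continue
                shifts = adduct_shift_set(m1["mode"], m2["mode"], setting, cfg.adduct_table)
                resid = np.abs((m1["mz"] - m2["mz"]) - shifts)
                if resid.min() <= cfg.tolerance:
                    out[s2] = (float(shifts[resid.argmin()]), float(resid.min()))
            if out:
                break
        return sorted(out.items())

    def direction(dsa, dsb, flip):
        best = {}
        for s1 in dsa.signal_ids:
            entries = []
            for s2, (d, resid) in cands_for(dsa, dsb, s1):
                r = corr(s1, s2, flip)
                if np.isfinite(r):
                    entries.append((-r, resid, s2, d))
            if not entries:
                continue
            entries.sort()
            neg_r, resid, s2, d = entries[0]
            if cfg.correlation_cutoff is not None and -neg_r <= cfg.correlation_cutoff:
                continue
            best[s1] = (s2, -neg_r, resid)
        return best

    def unique(best):
        by2 = {}
        for s1, (s2, r, resid) in best.items():
            by2.setdefault(s2, []).append((-r, resid, s1))
        out = {}
        for s2, lst in by2.items():
            lst.sort()
            out[lst[0][2]] = best[lst[0][2]]
        return out

    fwd = direction(ds1, ds2, flip=False)
    if cfg.match_type == "multiple":
        return {s1: v[0] for s1, v in fwd.items()}
    if cfg.match_type == "unique":
        return {s1: v[0] for s1, v in unique(fwd).items()}
    rev = unique(direction(ds2, ds1, flip=True))
    uf = unique(fwd)
    return {
        s1: v[0]
        for s1, v in uf.items()
        if v[0] in rev and rev[v[0]][0] == s1
    }


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("match_type", ["multiple", "unique", "reciprocal"])
@pytest.mark.parametrize("corr_setting", ["dataset1", "all"])
def test_match_signals_equals_brute_force(seed, match_type, corr_setting):
    ds1, ds2 = _pair_datasets(seed=seed, n_extra1=5, n_extra2=6)
    cfg = MatchConfig(
        adduct_setting="adduct", correlation_setting=corr_setting, match_type=match_type
    )
    imp = CrossImputer(ds1, ds2)
    res = match_signals(ds1, ds2, cfg, imputer=imp)
    got = dict(zip(res.pairs["signal1_id"], res.pairs["signal2_id"]))
    assert got == brute_force_match(ds1, ds2, cfg, imp)


class TestMatchSignals:
    def test_spec_toy_best_correlated_wins(self):
        # D1 signal A vs D2 candidates X (r = 0.90) and Y (r = 0.95): Y wins
        rng = np.random.default_rng(0)
        n = 200
        shared = {k: rng.standard_normal(n) for k in ("ala", "gly", "ser")}
        a = rng.standard_normal(n)

        def noisy(v, rho):
            z = rng.standard_normal(n)
            return rho * v + np.sqrt(1 - rho**2) * z

        d1 = make_dataset(
            {"d1_A": a, **{f"d1_{k}": v for k, v in shared.items()}},
            {
                "d1_A": {"mz": 100.0, "mode": "positive", "method": "M", "known_name": None},
                **{
                    f"d1_{k}": {"mz": 200.0 + i, "mode": "positive", "method": "M",
                                "known_name": k}
                    for i, k in enumerate(shared)
                },
            },
        )
        d2 = make_dataset(
            {"d2_X": noisy(a, 0.90), "d2_Y": noisy(a, 0.95),
             **{f"d2_{k}": v for k, v in shared.items()}},
            {
                "d2_X": {"mz": 100.0010, "mode": "positive", "method": "M", "known_name": None},
                "d2_Y": {"mz": 100.0040, "mode": "positive", "method": "M", "known_name": None},
                **{
                    f"d2_{k}": {"mz": 200.0 + i, "mode": "positive", "method": "M",
                                "known_name": k}
                    for i, k in enumerate(shared)
                },
            },
        )
        imp = CrossImputer(d1, d2)
        # force the imputations to reproduce the intended correlations exactly
        imp.imputed_2_in_1["d2_X"] = d2.abundance["d2_X"].to_numpy()
        imp.imputed_2_in_1["d2_Y"] = d2.abundance["d2_Y"].to_numpy()
        cfg = MatchConfig(adduct_setting="no_adduct", correlation_setting="dataset1",
                          match_type="multiple")
        res = match_signals(d1, d2, cfg, imputer=imp, query_signals1=["d1_A"])
        assert dict(zip(res.pairs["signal1_id"], res.pairs["signal2_id"])) == {"d1_A": "d2_Y"}
        # a cutoff above both correlations leaves A unmatched
        cfg2 = MatchConfig(adduct_setting="no_adduct", correlation_setting="dataset1",
                           match_type="multiple", correlation_cutoff=0.99)
        res2 = match_signals(d1, d2, cfg2, imputer=imp, query_signals1=["d1_A"])
        assert len(res2.pairs) == 0

    @pytest.mark.parametrize("seed", [0, 5])
    def test_containment_reciprocal_unique_multiple(self, seed):
        ds1, ds2 = _pair_datasets(seed=seed, n_extra1=6, n_extra2=6)
        imp = CrossImputer(ds1, ds2)
        results = {}
        for mt in ("multiple", "unique", "reciprocal"):
            res = match_signals(ds1, ds2, MatchConfig(match_type=mt), imputer=imp)
            results[mt] = set(zip(res.pairs["signal1_id"], res.pairs["signal2_id"]))
        assert results["reciprocal"] <= results["unique"] <= results["multiple"]

    def test_reciprocal_is_injective(self, sim_pair_small):
        ds1, ds2, truth, _ = sim_pair_small
        res = match_signals(ds1, ds2, MatchConfig(match_type="reciprocal"))
        assert res.pairs["signal1_id"].is_unique
        assert res.pairs["signal2_id"].is_unique

    def test_multiple_output_bounded_by_ds1_signals(self, sim_pair_small):
        ds1, ds2, truth, _ = sim_pair_small
        res = match_signals(ds1, ds2, MatchConfig(match_type="multiple"))
        assert len(res.pairs) <= ds1.n_signals
        assert res.pairs["signal1_id"].is_unique


class TestMatchByRT:
    def test_exact_shift_line_candidate_wins(self):
        ds1, ds2 = _pair_datasets(seed=9)
        # RT2 = 2 + 1.1 * RT1 exactly for the knowns
        for k in ("ala", "gly", "ser", "thr"):
            ds2.meta.loc[f"d2_{k}", "rt"] = 2 + 1.1 * ds1.meta.loc[f"d1_{k}", "rt"]
        # candidate u0 sits exactly on the line for query u0
        ds1.meta.loc["d1_u0", "rt"] = 3.0
        ds2.meta.loc["d2_u0", "mz"] = ds1.meta.loc["d1_u0", "mz"]
        ds2.meta.loc["d2_u0", "rt"] = 2 + 1.1 * 3.0
        res = match_by_rt(ds1, ds2, MatchConfig(match_type="multiple"),
                          query_signals1=["d1_u0"])
        got = dict(zip(res.pairs["signal1_id"], res.pairs["signal2_id"]))
        assert got["d1_u0"] == "d2_u0"

    def test_no_candidates_unmatched(self):
        ds1, ds2 = _pair_datasets()
        ds1.meta.loc["d1_u0", "mz"] = 777.7777
        res = match_by_rt(ds1, ds2, MatchConfig(match_type="multiple"),
                          query_signals1=["d1_u0"])
        assert len(res.pairs) == 0

    def test_too_few_rt_knowns_error(self):
        ds1, ds2 = _pair_datasets()
        ds1.meta["rt"] = np.nan
        with pytest.raises(ValidationError, match="shared knowns with RT"):
            match_by_rt(ds1, ds2, MatchConfig())


class TestCalibration:
    def test_noiseless_duplicate_dataset_perfect(self):
        ds1, _ = _pair_datasets(seed=10)
        ab2 = ds1.abundance.copy()
        ab2.columns = [c.replace("d1_", "d2_") for c in ab2.columns]
        meta2 = ds1.meta.copy()
        meta2.index = ab2.columns
        from mspair import ProfilingDataset
        ds2 = ProfilingDataset(ab2, meta2, name="dup")
        grid = [MatchConfig(adduct_setting="no_adduct", correlation_setting="all",
                            match_type="reciprocal")]
        rows = calibrate_matching(ds1, ds2, grid)
        assert rows.loc[0, "correct_fraction"] == 1.0
        assert rows.loc[0, "rsq08_fraction"] == 1.0

    def test_correct_never_exceeds_rsq08(self, sim_pair_small):
        ds1, ds2, truth, _ = sim_pair_small
        grid = [
            MatchConfig(adduct_setting=a, correlation_setting="all", match_type=m)
            for a in ("no_adduct", "adduct") for m in ("multiple", "reciprocal")
        ]
        rows = calibrate_matching(ds1, ds2, grid)
        assert (rows["correct_fraction"] <= rows["rsq08_fraction"] + 1e-12).all()
        assert (rows["rsq08_fraction"] <= 1.0).all()

    def test_five_known_toy_with_decoy_by_hand(self):
        # 5 shared knowns and one decoy signal colliding with "ala"; the
        # decoy equals an independent latent so every known should match
        # itself; verified against exhaustive evaluation
        rng = np.random.default_rng(11)
        n = 120
        knowns = ["ala", "gly", "ser", "thr", "val"]
        lat = {k: rng.standard_normal(n) for k in knowns}
        decoy1 = rng.standard_normal(n)
        decoy2 = rng.standard_normal(n)

        def build(tag, decoy):
            vals = {f"{tag}_{k}": lat[k] + 0.1 * rng.standard_normal(n) for k in knowns}
            meta = {
                f"{tag}_{k}": {"mz": 100.0 + 10 * i + PROTON_MASS, "mode": "positive",
                               "method": "M", "known_name": k}
                for i, k in enumerate(knowns)
            }
            vals[f"{tag}_decoy"] = decoy
            meta[f"{tag}_decoy"] = {"mz": 100.0 + PROTON_MASS + 0.002, "mode": "positive",
                                    "method": "M", "known_name": None}
            return make_dataset(vals, meta, name=tag)

        ds1, ds2 = build("d1", decoy1), build("d2", decoy2)
        grid = [MatchConfig(adduct_setting="no_adduct", correlation_setting="all",
                            match_type="multiple")]
        rows = calibrate_matching(ds1, ds2, grid)
        assert rows.loc[0, "match_count"] == 5
        assert rows.loc[0, "correct_fraction"] == 1.0

    def test_rt_and_imputation_agree_on_noiseless_exact_shift(self):
        ds1, _ = _pair_datasets(seed=12)
        ab2 = ds1.abundance.copy()
        ab2.columns = [c.replace("d1_", "d2_") for c in ab2.columns]
        meta2 = ds1.meta.copy()
        meta2.index = ab2.columns
        meta2["rt"] = 2 + 1.1 * ds1.meta["rt"].to_numpy()
        from mspair import ProfilingDataset
        ds2 = ProfilingDataset(ab2, meta2, name="dup")
        grid = [MatchConfig(adduct_setting="no_adduct", correlation_setting="all",
                            match_type="reciprocal")]
        corr_rows = calibrate_matching(ds1, ds2, grid, matcher="correlation")
        rt_rows = calibrate_matching(ds1, ds2, grid, matcher="rt")
        assert corr_rows.loc[0, "correct_fraction"] == rt_rows.loc[0, "correct_fraction"] == 1.0
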