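import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from morphnet.inference import (
    bh_fdr,
    detect_hubs,
    group_effect_lm,
    hub_ttests,
    partial_correlation,
)

from oracles import bh_by_hand, pooled_t_by_hand


def cohort_frame(n_low, n_high, rng, extra=None):
    n = n_low + n_high
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "stress_group": ["Low"] * n_low + ["High"] * n_high,
            "age": rng.uniform(14, 15, n),
            "sex": rng.choice(["F", "M"], n),
            "site": rng.choice(["site1", "site2"], n),
            "PDS": rng.normal(16, 2.7, n),
            "SES": rng.normal(7, 3, n),
        }
    )
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


class TestDetectHubs:
    def test_outlier_is_hub(self):
        vals = np.ones((4, 400))
        vals[:, 17] = 10.0
        hubs = detect_hubs(vals, ["Low", "Low", "High", "High"])
        np.testing.assert_array_equal(hubs, [17])

    def test_all_equal_no_hubs(self):
        vals = np.full((4, 10), 3.0)
        assert len(detect_hubs(vals, ["Low", "Low", "High", "High"])) == 0

    def test_fixture_vector_direct_arithmetic(self, rng):
        means = rng.normal(size=20)
        means[5] += 10
        vals = np.tile(means, (6, 1))
        expected = set(np.flatnonzero(means > means.mean() + 2 * means.std(ddof=1)))
        hubs = detect_hubs(vals, ["Low"] * 3 + ["High"] * 3)
        assert set(hubs) == expected

    def test_union_across_groups(self):
        vals = np.ones((4, 50))
        vals[0:2, 3] = 30.0  # hub in Low only
        vals[2:4, 7] = 30.0  # hub in High only
        hubs = detect_hubs(vals, ["Low", "Low", "High", "High"])
        np.testing.assert_array_equal(hubs, [3, 7])

    def test_needs_two_nodes(self):
        with pytest.raises(ValueError):
            detect_hubs(np.ones((4, 1)), ["Low", "Low", "High", "High"])


class TestGroupEffectLM:
    def test_no_covariates_equals_pooled_t(self, rng):
        df = cohort_frame(10, 8, rng)
        y = rng.normal(size=18)
        res = group_effect_lm(y, df, covariates=())
        lo = y[:10]
        hi = y[10:]
        t_ref = pooled_t_by_hand(list(hi), list(lo))  # High-minus-Low orientation
        assert res.statistic == pytest.approx(t_ref, abs=1e-10)
        t_scipy, p_scipy = sps.ttest_ind(hi, lo, equal_var=True)
        assert res.statistic == pytest.approx(t_scipy, abs=1e-10)
        assert res.p == pytest.approx(p_scipy, abs=1e-10)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        df = cohort_frame(15, 15, rng)
        y = rng.normal(size=30) + 0.5 * (df["stress_group"] == "High")
        res = group_effect_lm(y, df, covariates=["age", "sex", "PDS"])
        x = pd.DataFrame(
            {
                "const": 1.0,
                "group": (df["stress_group"] == "High").astype(float),
                "age": df["age"],
                "sex": (df["sex"] == "M").astype(float),
                "PDS": df["PDS"],
            }
        )
        fit = sm.OLS(y, x).fit()
        assert res.estimate == pytest.approx(fit.params["group"], abs=1e-10)
        assert res.statistic == pytest.approx(fit.tvalues["group"], abs=1e-8)
        assert res.p == pytest.approx(fit.pvalues["group"], abs=1e-10)

    def test_recovers_known_effect(self, rng):
        gamma = 1.3
        df = cohort_frame(100, 100, rng)
        ind = (df["stress_group"] == "High").to_numpy(float)
        y = gamma * ind + rng.normal(size=200)
        res = group_effect_lm(y, df, covariates=["age", "sex"])
        se = res.estimate / res.statistic
        assert abs(res.estimate - gamma) < 3 * se

    def test_orthogonal_covariate_leaves_estimate(self, rng):
        df = cohort_frame(20, 20, rng)
        ind = (df["stress_group"] == "High").to_numpy(float)
        y = rng.normal(size=40)
        cov = rng.normal(size=40)
        # orthogonalize against [1, group]
        x = np.column_stack([np.ones(40), ind])
        cov = cov - x @ np.linalg.lstsq(x, cov, rcond=None)[0]
        base = group_effect_lm(y, df, covariates=())
        df2 = df.assign(orth=cov)
        with_cov = group_effect_lm(y, df2, covariates=["orth"])
        assert with_cov.estimate == pytest.approx(base.estimate, abs=1e-10)

    def test_collinear_covariates_named(self, rng):
        df = cohort_frame(5, 5, rng)
        df["age_copy"] = df["age"]
        with pytest.raises(ValueError, match="collinear"):
            group_effect_lm(rng.normal(size=10), df, covariates=["age", "age_copy"])

    def test_degenerate_constant_outcome(self, rng):
        df = cohort_frame(5, 5, rng)
        res = group_effect_lm(np.full(10, 2.5), df, covariates=())
        assert res.statistic == 0.0 and res.p == 1.0
        assert res.extra.get("degenerate")

    def test_small_group_rejected(self, rng):
        df = cohort_frame(1, 9, rng)
        with pytest.raises(ValueError, match="fewer than 2"):
            group_effect_lm(rng.normal(size=10), df, covariates=())


class TestHubTTests:
    def test_textbook_formula(self, rng):
        lo = rng.normal(size=(8, 3))
        hi = rng.normal(size=(6, 3))
        vals = np.vstack([lo, hi])
        groups = ["Low"] * 8 + ["High"] * 6
        res = hub_ttests(vals, groups, nodes=[0, 1, 2])
        for k, r in enumerate(res):
            expected = pooled_t_by_hand(list(lo[:, k]), list(hi[:, k]))
            assert r.statistic == pytest.approx(expected, abs=1e-10)

    def test_family_fdr_filled(self, rng):
        vals = rng.normal(size=(12, 5))
        groups = ["Low"] * 6 + ["High"] * 6
        res = hub_ttests(vals, groups, nodes=list(range(5)), family="BC@0.05")
        raw = [r.p for r in res]
        adj, _ = bh_fdr(raw)
        for r, a in zip(res, adj):
            assert r.p_corr == pytest.approx(a)
            assert r.p_corr >= r.p - 1e-15

    def test_null_uniformity(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(40, 1000))
        groups = ["Low"] * 20 + ["High"] * 20
        res = hub_ttests(vals, groups, nodes=list(range(1000)))
        frac = np.mean([r.p < 0.05 for r in res])
        assert abs(frac - 0.05) < 0.02

    def test_planted_shift_found(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            vals = rng.normal(size=(80, 50))
            vals[40:, 7] += 2.0  # d = 2 at node 7, n = 40/group
            groups = ["Low"] * 40 + ["High"] * 40
            res = hub_ttests(vals, groups, nodes=list(range(50)))
            best = min(res, key=lambda r: r.p)
            hits += best.extra["node"] == 7
        assert hits >= 19

    def test_empty_nodes(self, rng):
        vals = rng.normal(size=(8, 4))
        assert hub_ttests(vals, ["Low"] * 4 + ["High"] * 4, nodes=[]) == []

    def test_small_group_rejected(self, rng):
        vals = rng.normal(size=(3, 4))
        with pytest.raises(ValueError, match="at least 2"):
            hub_ttests(vals, ["Low", "High", "High"], nodes=[0])


class TestBHFDR:
    def test_hand_worked_example(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.50]
        adj, reject = bh_fdr(p, q=0.05)
        assert reject[:4].all() and not reject[4]
        assert set(bh_by_hand(p, 0.05)) == {0, 1, 2, 3}

    def test_matches_statsmodels(self, rng):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=200)
        adj, reject = bh_fdr(p, q=0.05)
        ref_reject, ref_adj, *_ = mt.multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, ref_adj, atol=1e-12)
        np.testing.assert_array_equal(reject, ref_reject)

    def test_all_ones(self):
        adj, reject = bh_fdr([1.0] * 5)
        assert not reject.any()
        np.testing.assert_array_equal(adj, 1.0)

    def test_single_p(self):
        adj, _ = bh_fdr([0.031])
        assert adj[0] == pytest.approx(0.031)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_monotone_and_dominates_raw(self, p):
        adj, _ = bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_agreement_with_hand_rule_random(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30)).tolist()
            _, reject = bh_fdr(p, q=0.05)
            assert set(np.flatnonzero(reject)) == bh_by_hand(p, 0.05)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestPartialCorrelation:
    def test_empty_z_equals_pearson(self, rng):
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        r, p = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_recovers_known_partial(self):
        rng = np.random.default_rng(123)
        n = 500
        z = rng.normal(size=n)
        u1 = rng.normal(size=n)
        u2 = rng.normal(size=n)
        rho = 0.5
        x = z + u1
        y = z + rho * u1 + np.sqrt(1 - rho**2) * u2
        r, _ = partial_correlation(x, y, z)
        assert abs(r - rho) < 0.08

    def test_exact_linear_function_of_z(self, rng):
        z = rng.normal(size=(60, 2))
        x = rng.normal(size=60)
        y = 2.0 + z @ np.array([1.5, -0.7])
        r, p = partial_correlation(x, y, z)
        assert abs(r) < 1e-10

    def test_matches_pingouin_convention(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=80)
        zc = rng.normal(size=80)
        y = 0.3 * x + 0.5 * zc + rng.normal(size=80)
        df = pd.DataFrame({"x": x, "y": y, "z": zc})
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        r, p = partial_correlation(x, y, zc)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_sample_size_guard(self, rng):
        with pytest.raises(ValueError, match="n >"):
            partial_correlation([1, 2, 3], [1, 2, 3], np.ones((3, 2)))

    def test_rank_deficient_z(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        z = np.column_stack([np.arange(20), np.arange(20) * 2.0])
        with pytest.raises(ValueError, match="rank deficient"):
            partial_correlation(x, y, z)
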