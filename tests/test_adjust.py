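import numpy as np
import pandas as pd
import pytest

from mtkit.adjust import (
    ALPHA_BONFERRONI_40,
    BLOOD_COLUMNS,
    DesignConfig,
    build_design,
    carrier_phenotype_test,
    carrier_phenotype_tests,
    disease_association,
    gated_adjust,
    natural_spline_basis,
    rescale_adjusted,
    residualize_demographics,
)
from mtkit.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(SimConfig(n_samples=3000, seed=11))


class TestNaturalSplineBasis:
    def test_df_gives_df_columns(self, rng):
        x = rng.uniform(0, 10, size=200)
        assert natural_spline_basis(x, df=5).shape == (200, 5)

    def test_linear_function_in_column_span(self, rng):
        x = rng.uniform(0, 10, size=200)
        B = natural_spline_basis(x, df=5)
        X = np.column_stack([np.ones_like(x), B])
        y = 3.0 * x - 1.0
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(resid).max() < 1e-8

    def test_matches_piecewise_cubic_evaluation(self):
        # independent oracle: evaluate the truncated-power construction
        # directly at interior knots
        x = np.linspace(0, 1, 101)
        knots = np.array([0.25, 0.5, 0.75])
        B = natural_spline_basis(x, knots=knots, boundary_knots=(0.0, 1.0))
        allk = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        K = len(allk)

        def d(k, t):
            return (np.clip(t - allk[k], 0, None) ** 3
                    - np.clip(t - allk[K - 1], 0, None) ** 3) / (allk[K - 1] - allk[k])

        for t_idx in [25, 50, 75]:
            t = x[t_idx]
            expect = [t] + [d(k, t) - d(K - 2, t) for k in range(K - 2)]
            assert np.allclose(B[t_idx], expect)

    def test_linear_beyond_boundary_knots(self):
        x = np.linspace(-5, 15, 400)
        B = natural_spline_basis(x, knots=[3.0, 5.0, 7.0],
                                 boundary_knots=(0.0, 10.0))
        left = x < -1
        for j in range(B.shape[1]):
            col = B[left, j]
            second_diff = np.diff(col, 2)
            assert np.abs(second_diff).max() < 1e-8

    def test_spans_same_space_as_patsy_cr(self, rng):
        # independent implementation oracle: both bases span the natural
        # cubic spline space, so cross-projection residuals vanish
        import patsy
        x = np.sort(rng.uniform(0, 1, 300))
        knots = np.array([0.2, 0.4, 0.6, 0.8])
        mine = natural_spline_basis(x, knots=knots, boundary_knots=(0.0, 1.0))
        theirs = np.asarray(patsy.dmatrix(
            "cr(x, knots=k, lower_bound=0, upper_bound=1) - 1",
            {"x": x, "k": knots}))
        A = np.column_stack([np.ones_like(x), mine])
        for j in range(theirs.shape[1]):
            r = theirs[:, j] - A @ np.linalg.lstsq(A, theirs[:, j], rcond=None)[0]
            assert np.abs(r).max() < 1e-6

    def test_too_few_distinct_values_errors(self):
        with pytest.raises(ValueError):
            natural_spline_basis(np.array([1.0, 1.0, 2.0]), df=5)


class TestBuildDesign:
    def test_fasting_recodes(self, cohort):
        meta = cohort["metadata"].head(50).copy()
        meta.loc[meta.index[0], "fasting_time"] = 22  # capped to 18
        meta.loc[meta.index[1], "fasting_time"] = 0   # floored to 1
        X, _ = build_design(meta, model="technical")
        fast_cols = [c for c in X.columns if c.startswith("fasting_")]
        row0 = X.loc[meta.index[0], fast_cols]
        assert row0.get("fasting_18", 0) == 1.0
        assert not any(c in X.columns for c in ["fasting_22", "fasting_0"])

    def test_blood_outlier_masks_row(self, cohort):
        meta = cohort["metadata"].head(200).copy()
        col = BLOOD_COLUMNS[4]  # neutrophil percentage
        meta[col] = np.random.default_rng(0).standard_normal(len(meta))
        meta.loc[meta.index[3], col] = 40.0  # Z far above 4
        _, mask = build_design(meta, model="blood")
        assert not mask.iloc[3]
        assert mask.drop(meta.index[3]).all()

    def test_joint_contains_both_term_groups(self, cohort):
        X, _ = build_design(cohort["metadata"].head(100), model="joint")
        assert any(c.startswith("ns_draw_time") for c in X.columns)
        assert any(c.startswith("ns_date") for c in X.columns)
        assert set(BLOOD_COLUMNS) <= set(X.columns)

    def test_seasonal_knot_validation(self):
        with pytest.raises(ValueError):
            DesignConfig(seasonal_knots=["2009-01-01", "2008-01-01"])


class TestGatedAdjust:
    def test_gating_decision(self, cohort):
        meta = cohort["metadata"]
        X, mask = build_design(meta, model="joint")
        adjusted, report = gated_adjust(meta["mtcn"], X, scale="log",
                                        row_mask=mask, trait="mtcn")
        assert report.f_pvalue < ALPHA_BONFERRONI_40
        assert report.gated

    def test_null_trait_not_gated(self, cohort, rng):
        meta = cohort["metadata"]
        X, mask = build_design(meta, model="joint")
        y = rng.standard_normal(len(meta))  # independent of every covariate
        adjusted, report = gated_adjust(y, X, row_mask=mask)
        if not report.gated:
            used = adjusted[mask].to_numpy()
            assert np.allclose(used, y[mask.to_numpy()])

    def test_residuals_orthogonal_to_design(self, cohort):
        meta = cohort["metadata"]
        X, mask = build_design(meta, model="joint")
        adjusted, report = gated_adjust(meta["mtcn"], X, scale="log",
                                        row_mask=mask)
        used = adjusted.notna()
        r = adjusted[used].to_numpy()
        for c in X.columns:
            col = X.loc[used, c].to_numpy(float)
            if col.std() == 0:
                continue
            corr = np.corrcoef(r, col)[0, 1]
            assert abs(corr) < 1e-10

    def test_rank_deficient_design_errors(self, cohort):
        meta = cohort["metadata"].head(100)
        X, _ = build_design(meta, model="blood")
        X["dup"] = X[BLOOD_COLUMNS[0]]
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            gated_adjust(meta["mtcn"], X)


class TestRescale:
    def test_zero_residual_returns_exp_mean(self):
        m = np.log(61.66)
        assert rescale_adjusted(np.zeros(3), m, "exp_add_mean") == \
            pytest.approx(np.exp(m))

    def test_add_mean_on_zero_residuals(self):
        out = rescale_adjusted(np.zeros(5), 4.2, "add_mean")
        assert np.allclose(out, 4.2)

    def test_round_trip_against_empty_design(self, rng):
        y = rng.uniform(10, 100, size=200)
        X = pd.DataFrame(index=pd.RangeIndex(200))
        adjusted, report = gated_adjust(y, X, scale="log")
        back = rescale_adjusted(adjusted.to_numpy(), np.log(y).mean(),
                                "exp_add_mean")
        assert np.allclose(back, y, rtol=1e-12)


class TestResidualizeDemographics:
    def _samples(self, rng, n=2000):
        return pd.DataFrame({
            "age": rng.uniform(40, 70, n),
            "sex": rng.integers(0, 2, n),
            "population": rng.choice(["EUR", "AFR"], n),
        }, index=pd.RangeIndex(n))

    def test_linear_in_age_becomes_constant(self, rng):
        s = self._samples(rng)
        y = 2.0 + 0.5 * s["age"]
        out = residualize_demographics(y, s)
        assert np.allclose(out, y.mean(), atol=1e-8)

    def test_left_right_average(self, rng):
        s = self._samples(rng, 2)
        m = pd.DataFrame({"left": [10.0, 20.0], "right": [14.0, 20.0]},
                         index=s.index)
        out = residualize_demographics(m, s, lr_average=True)
        assert out.notna().all()  # averaged to (12, 20) before modelling

    def test_planted_sex_effect_removed(self, rng):
        s = self._samples(rng)
        y = 5.0 + 1.5 * s["sex"] + rng.normal(0, 1, len(s))
        out = residualize_demographics(y, s)
        male = out[s["sex"] == 1]
        female = out[s["sex"] == 0]
        t = (male.mean() - female.mean()) / np.sqrt(
            male.var() / len(male) + female.var() / len(female))
        assert abs(t) < 1e-6


class TestCarrierTests:
    def test_too_few_carriers_not_tested(self, rng):
        res = carrier_phenotype_test(rng.normal(size=9), rng.normal(size=500))
        assert not res.tested

    def test_ten_is_still_too_few(self, rng):
        res = carrier_phenotype_test(rng.normal(size=10), rng.normal(size=500))
        assert not res.tested  # strictly more than ten required

    def test_identical_groups_give_null_statistics(self):
        vals = np.arange(100.0)
        res = carrier_phenotype_test(vals, vals)
        assert abs(res.t_statistic) < 1e-12
        assert res.p_value > 0.99

    def test_planted_shift_detected(self, rng):
        detected = 0
        for i in range(10):
            r = np.random.default_rng(i)
            carriers = r.normal(1.0, 1.0, 100)
            controls = r.normal(0.0, 1.0, 10_000)
            res = carrier_phenotype_test(carriers, controls)
            if res.p_value < 1e-3:
                detected += 1
        assert detected >= 9

    def test_bh_applied_across_tested_set(self, rng):
        pairs = [(rng.normal(size=50), rng.normal(size=500), f"v{i}", "trait")
                 for i in range(5)]
        pairs.append((rng.normal(size=5), rng.normal(size=500), "small", "trait"))
        results = carrier_phenotype_tests(pairs)
        qs = [r.q_value for r in results if r.tested]
        assert len(qs) == 5 and all(q is not None for q in qs)
        assert results[-1].q_value is None


class TestDiseaseAssociation:
    def _simulate(self, seed, n=4000, log_or=0.3):
        r = np.random.default_rng(seed)
        s = pd.DataFrame({
            "age": r.uniform(40, 70, n),
            "sex": r.integers(0, 2, n),
            "population": r.choice(["EUR", "AFR"], n),
        })
        z = r.standard_normal(n)
        age_c = (s["age"] - 55) / 10
        logit = -2.0 + log_or * z + 0.2 * age_c
        y = (r.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        return s, z, y

    def test_null_effect_gives_or_near_one(self):
        s, z, y = self._simulate(0, log_or=0.0)
        res = disease_association(z, y, s)
        assert res.ci_low < 1.0 < res.ci_high

    def test_planted_log_or_recovered_within_ci(self):
        covered = 0
        for seed in range(10):
            s, z, y = self._simulate(seed, log_or=0.3)
            res = disease_association(z, y, s)
            if res.ci_low <= np.exp(0.3) <= res.ci_high:
                covered += 1
        assert covered >= 9

    def test_small_haplogroups_excluded(self, rng):
        s, z, y = self._simulate(1, n=500)
        hap = pd.Series(["H"] * 471 + ["Z"] * 29, index=s.index)
        res = disease_association(z, y, s, haplogroup=hap)
        assert res.n == 471

    def test_separation_flagged(self):
        n = 200
        r = np.random.default_rng(3)
        s = pd.DataFrame({"age": r.uniform(40, 70, n),
                          "sex": r.integers(0, 2, n)})
        z = np.linspace(-3, 3, n)
        y = (z > 0).astype(float)  # perfectly separable
        res = disease_association(z, y, s)
        assert res.separated and res.odds_ratio is None
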