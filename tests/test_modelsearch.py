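"""Equation-search machinery tests."""

import numpy as np
import pandas as pd
import pytest

import gfrkit.modelsearch as ms


def brute_force_count(pool, constraints):
    """Stream the enumerator, validating each formula independently."""
    seen = set()
    for f in ms.enumerate_formulas(pool, constraints):
        assert ms.validate_formula(f, constraints), f.describe()
        assert f not in seen, f"duplicate {f.describe()}"
        seen.add(f)
    return len(seen)


class TestEnumeration:
    def test_single_parameter_pool_is_empty(self):
        # {raw, log} of one parameter is forbidden; no interaction partner
        pool = ms.FeaturePool(("a",))
        assert brute_force_count(pool, ms.SearchConstraints()) == 0
        assert ms.count_formulas(pool) == 0

    def test_two_parameter_pool(self):
        pool = ms.FeaturePool(("a", "b"))
        assert brute_force_count(pool, ms.SearchConstraints()) == 32
        assert ms.count_formulas(pool) == 32

    @pytest.mark.parametrize("P", range(1, 6))
    @pytest.mark.parametrize("allow_inter", [True, False])
    @pytest.mark.parametrize("allow_self", [True, False])
    def test_stream_matches_closed_form(self, P, allow_inter, allow_self):
        pool = ms.FeaturePool(tuple("abcde"[:P]))
        cons = ms.SearchConstraints(allow_interactions=allow_inter,
                                    allow_self_interaction=allow_self)
        assert brute_force_count(pool, cons) == ms.count_formulas(pool, cons)

    def test_full_pool_closed_form(self):
        assert ms.count_formulas(ms.FeaturePool()) == 487_008

    def test_no_interactions_full_pool(self):
        cons = ms.SearchConstraints(allow_interactions=False)
        assert ms.count_formulas(ms.FeaturePool(), cons) == 25_128

    def test_duplicate_pool_parameters_rejected(self):
        with pytest.raises(ValueError):
            ms.FeaturePool(("a", "a"))


def make_linear_cohort(n, seed, noise=0.0):
    """Cohort from a known log-linear model: ln(y) = 2 + 0.5 ln(x1) - 0.3 x2."""
    rng = np.random.default_rng(seed)
    x1 = np.exp(rng.normal(0, 0.5, n))
    x2 = rng.normal(1.0, 0.3, n)
    y = np.exp(2.0 + 0.5 * np.log(x1) - 0.3 * x2 + rng.normal(0, noise, n))
    return pd.DataFrame({"x1": x1, "x2": x2, "mgfr_ml_min_173": y})


FORMULA = ms.ModelFormula((("x1", "log"), ("x2", "raw")), None, "log")


class TestFit:
    def test_noiseless_exact_recovery(self):
        cand = ms.fit_formula(FORMULA, make_linear_cohort(100, 0))
        np.testing.assert_allclose(
            cand.coefficients[["const", "log(x1)", "x2"]], [2.0, 0.5, -0.3],
            rtol=1e-8)
        assert cand.train_mae == pytest.approx(0.0, abs=1e-8)
        assert cand.train_p30 == 100.0

    def test_collinear_design_rejected(self):
        df = make_linear_cohort(50, 1)
        df["x2"] = 2.0 * df["x1"]  # duplicated information
        f = ms.ModelFormula((("x1", "raw"), ("x2", "raw")), None, "raw")
        with pytest.raises(np.linalg.LinAlgError):
            ms.fit_formula(f, df)

    def test_residuals_orthogonal_to_design(self):
        df = make_linear_cohort(200, 2, noise=0.2)
        f = ms.ModelFormula((("x1", "raw"), ("x2", "raw")), None, "raw")
        cand = ms.fit_formula(f, df)
        X = ms.design_matrix(f, df).to_numpy()
        resid = df["mgfr_ml_min_173"].to_numpy() - cand.predict(df)
        np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-6)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            ms.fit_formula(FORMULA, make_linear_cohort(3, 0))


class TestCrossValidation:
    def test_noiseless_cv_mae_zero(self):
        r = ms.cross_validate(FORMULA, make_linear_cohort(120, 0), seed=5)
        assert r["cv_mae_mean"] == pytest.approx(0.0, abs=1e-8)

    def test_seeded_determinism(self):
        df = make_linear_cohort(120, 1, noise=0.2)
        a = ms.cross_validate(FORMULA, df, seed=9)
        b = ms.cross_validate(FORMULA, df, seed=9)
        np.testing.assert_array_equal(a["fold_maes"], b["fold_maes"])

    def test_fold_count(self):
        df = make_linear_cohort(120, 1, noise=0.2)
        r = ms.cross_validate(FORMULA, df, repeats=5, folds=5, seed=0)
        assert r["fold_maes"].size == 25

    def test_matches_theoretical_mae(self):
        # raw-scale additive noise: E|err| of the true model ~ sqrt(2/pi)*sd
        rng = np.random.default_rng(7)
        n, sd = 2000, 5.0
        x = rng.normal(10, 2, n)
        y = 50 + 3 * x + rng.normal(0, sd, n)
        df = pd.DataFrame({"x1": x, "mgfr_ml_min_173": y, "x2": rng.normal(size=n)})
        f = ms.ModelFormula((("x1", "raw"), ("x2", "raw")), None, "raw")
        r = ms.cross_validate(f, df, seed=1)
        theory = np.sqrt(2 / np.pi) * sd
        assert abs(r["cv_mae_mean"] - theory) / theory < 0.2

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            ms.cross_validate(FORMULA, make_linear_cohort(10, 0))


def make_candidates(maes, seed=0):
    """Synthetic trained candidates with prescribed MAE values."""
    df = make_linear_cohort(60, seed, noise=0.1)
    base = ms.fit_formula(FORMULA, df)
    out = []
    for i, mae in enumerate(maes):
        c = ms.TrainedCandidate(
            formula=ms.ModelFormula((("x1", "log"), (f"p{i}", "raw")), None, "log"),
            coefficients=base.coefficients, bse=base.bse, n=60, sigma2=1.0,
            train_mae=mae, train_p15=50.0, train_p20=60.0, train_p30=80.0,
            het_score=0.1, upper_range_frac=0.9,
            cv_mae_mean=mae, cv_mae_cv=0.1)
        out.append(c)
    return out


class TestFilters:
    def test_empty_rules_identity(self):
        cands = make_candidates([5, 6, 7])
        surv, audit = ms.apply_filters(cands, [])
        assert surv == cands and audit.empty

    def test_threshold_below_minimum_empties(self):
        cands = make_candidates([5, 6, 7])
        surv, audit = ms.apply_filters(
            cands, [{"name": "kill", "field": "train_mae", "op": "le",
                     "threshold": 4.9}])
        assert surv == [] and audit.loc[0, "removed"] == 3

    def test_median_rule_removes_upper_half(self):
        maes = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        cands = make_candidates(maes)
        surv, _ = ms.apply_filters(
            cands, [{"name": "m", "field": "train_mae", "op": "le",
                     "threshold": float(np.median(maes))}])
        assert [c.train_mae for c in surv] == [1.0, 2.0, 3.0]

    def test_monotone_in_rules(self):
        cands = make_candidates([1, 2, 3, 4, 5])
        rules = [{"name": "a", "field": "train_mae", "op": "le", "threshold": 4},
                 {"name": "b", "field": "cv_mae_cv", "op": "le", "threshold": 0.2},
                 {"name": "c", "field": "train_p30", "op": "ge", "threshold": 50}]
        prev = len(cands)
        for k in range(len(rules) + 1):
            surv, _ = ms.apply_filters(cands, rules[:k])
            assert len(surv) <= prev
            prev = len(surv)

    def test_unknown_field_is_config_error(self):
        with pytest.raises(ms.FilterConfigError):
            ms.apply_filters(make_candidates([1.0]),
                             [{"name": "x", "field": "no_such", "op": "le",
                               "threshold": 1}])

    def test_redundancy_prunes_dominated_relative(self):
        cands = make_candidates([2.0, 5.0])
        # same log(x1) feature shared; second dominated on MAE at equal P20
        surv, _ = ms.apply_filters(
            cands, [{"name": "red", "kind": "redundancy",
                     "min_shared_features": 1}])
        assert [c.train_mae for c in surv] == [2.0]


class TestPiecewise:
    def test_structure_four_branches(self, equation_cohort):
        f = ms.ModelFormula(
            (("scys_mg_l", "log"), ("scr_umol_l", "log"),
             ("valine_umol_l", "log"), ("myo_inositol_umol_l", "raw"),
             ("age_years", "raw")), None, "log")
        cand = ms.fit_formula(f, equation_cohort)
        pw = ms.engineer_piecewise(cand, equation_cohort, pivot="scys_mg_l",
                                   cutoffs={"female": 1.02, "male": 1.22})
        assert len(pw.branches) == 4
        assert {(b.sex, b.side) for b in pw.branches} == {
            ("female", "below"), ("female", "at_or_above"),
            ("male", "below"), ("male", "at_or_above")}
        # shared terms appear once
        assert "log(scr_umol_l)" in pw.shared_coefficients.index

    def test_null_branch_effect(self):
        # data with no branch structure: branch exponents agree within 3 SE
        rng = np.random.default_rng(21)
        n = 1500
        x = np.exp(rng.normal(0.1, 0.4, n))
        z = np.exp(rng.normal(0.0, 0.3, n))
        y = np.exp(1.0 - 0.6 * np.log(x) + 0.4 * np.log(z)
                   + rng.normal(0, 0.1, n))
        df = pd.DataFrame({"piv": x, "z": z, "mgfr_ml_min_173": y,
                           "sex": np.where(rng.random(n) < 0.5, "F", "M")})
        f = ms.ModelFormula((("piv", "log"), ("z", "log")), None, "log")
        cand = ms.fit_formula(f, df)
        pw = ms.engineer_piecewise(cand, df, pivot="piv",
                                   cutoffs={"female": 1.0, "male": 1.0})
        exps = [b.pivot_exponent for b in pw.branches]
        ses = [b.pivot_exponent_se for b in pw.branches]
        for i in range(4):
            for j in range(i + 1, 4):
                se = np.hypot(ses[i], ses[j])
                assert abs(exps[i] - exps[j]) < 3 * se

    def test_prediction_roundtrip(self, equation_cohort):
        f = ms.ModelFormula((("scys_mg_l", "log"), ("scr_umol_l", "log")),
                            None, "log")
        cand = ms.fit_formula(f, equation_cohort)
        pw = ms.engineer_piecewise(cand, equation_cohort, pivot="scys_mg_l",
                                   cutoffs={"female": 1.02, "male": 1.22})
        pred = pw.predict(equation_cohort)
        assert pred.shape == (len(equation_cohort),)
        assert (pred > 0).all()

    def test_tiny_branch_rejected(self):
        df = pd.DataFrame({
            "piv": [0.5, 0.6, 0.7, 2.0, 0.5, 0.6, 0.8, 0.9],
            "z": np.arange(1.0, 9.0),
            "sex": ["F"] * 4 + ["M"] * 4,
            "mgfr_ml_min_173": np.arange(40.0, 48.0)})
        f = ms.ModelFormula((("piv", "log"), ("z", "log")), None, "log")
        with pytest.raises(ValueError, match="branch"):
            cand = ms.fit_formula(f, df)
            ms.engineer_piecewise(cand, df, pivot="piv",
                                  cutoffs={"female": 1.0, "male": 1.0})


class TestVuong:
    def test_identical_models_undefined(self):
        df = make_linear_cohort(80, 3, noise=0.1)
        cand = ms.fit_formula(FORMULA, df)
        with pytest.warns(UserWarning):
            out = ms.vuong_test(cand, cand, df)
        assert not out["defined"] and out["p"] == 1.0

    def test_hand_computed_statistic(self):
        df = pd.DataFrame({"x1": [1.0, 2.0, 3.0, 4.0, 5.0],
                           "x2": [0.1, 0.5, 0.2, 0.9, 0.4],
                           "mgfr_ml_min_173": [10.0, 19.0, 31.0, 39.0, 52.0]})
        fa = ms.ModelFormula((("x1", "raw"),), None, "raw")
        fb = ms.ModelFormula((("x2", "raw"),), None, "raw")
        ca, cb = ms.fit_formula(fa, df), ms.fit_formula(fb, df)
        out = ms.vuong_test(ca, cb, df)

        # independent literal evaluation of the statistic
        def loglik(f, c):
            X = ms.design_matrix(f, df).to_numpy()
            r = df["mgfr_ml_min_173"].to_numpy() - X @ c.coefficients.to_numpy()
            s2 = np.mean(r ** 2)
            return -0.5 * np.log(2 * np.pi * s2) - r ** 2 / (2 * s2)

        d = loglik(fa, ca) - loglik(fb, cb)
        z = np.sqrt(5) * d.mean() / d.std(ddof=1)
        assert out["statistic"] == pytest.approx(z, rel=1e-12)

    def test_detects_missing_strong_predictor(self):
        # nested true model vs model lacking the strong term wins mostly
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            n = 500
            x1 = rng.normal(0, 1, n)
            x2 = rng.normal(0, 1, n)
            y = 50 + 8 * x1 + 1.0 * x2 + rng.normal(0, 3, n)
            df = pd.DataFrame({"x1": x1, "x2": x2, "mgfr_ml_min_173": y})
            full = ms.fit_formula(
                ms.ModelFormula((("x1", "raw"), ("x2", "raw")), None, "raw"), df)
            reduced = ms.fit_formula(
                ms.ModelFormula((("x2", "raw"),), None, "raw"), df)
            out = ms.vuong_test(full, reduced, df)
            if out["statistic"] > 0 and out["p"] < 0.05:
                wins += 1
        assert wins >= 18  # > 90% of simulations

    def test_mixed_response_transform_rejected(self):
        df = make_linear_cohort(80, 4, noise=0.1)
        a = ms.fit_formula(FORMULA, df)
        b = ms.fit_formula(ms.ModelFormula((("x1", "log"), ("x2", "raw")),
                                           None, "raw"), df)
        with pytest.raises(ValueError):
            ms.vuong_test(a, b, df)
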