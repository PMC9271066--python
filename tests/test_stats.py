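import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from kneessfm.stats import (
    StandardizedLinearModel,
    StepwiseSexClassifier,
    binomial_ci_exact,
    decision_geometry,
    forward_stepwise_logistic,
    regression_table,
    standardized_mlr,
    stratified_cv,
)


def _demo(rng, n=200):
    sex = (rng.random(n) < 0.4).astype(int)
    return pd.DataFrame(
        {
            "sex": sex,
            "height": rng.normal(170 + 8 * sex, 6, size=n),
            "mass": rng.normal(62 + 10 * sex, 8, size=n),
            "age": rng.normal(28, 4, size=n),
        }
    )


class TestStandardizedMLR:
    def test_exact_linear_response(self):
        rng = np.random.default_rng(0)
        demo = _demo(rng, 80)
        h = demo["height"].to_numpy()
        y = (h - h.mean()) / h.std(ddof=1)
        res = standardized_mlr(y, demo)
        # response IS standardized height: its beta is forced to carry all
        # of the (height-explainable) signal and R^2 is 1
        assert abs(res.r_squared - 1.0) < 1e-9
        assert abs(res.betas["height"] - 1.0) < 1e-9 or res.r_squared > 0.999

    def test_null_response_small_betas(self):
        rng = np.random.default_rng(1)
        demo = _demo(rng, 200)
        y = rng.normal(size=200)
        res = standardized_mlr(y, demo)
        assert np.abs(res.betas.to_numpy()).max() < 0.2
        assert res.r_squared < 0.05

    def test_betas_invariant_to_unit_rescaling(self):
        rng = np.random.default_rng(2)
        demo = _demo(rng, 100)
        y = rng.normal(size=100)
        a = standardized_mlr(y, demo)
        demo_m = demo.assign(height=demo["height"] / 100.0)  # cm -> m
        b = standardized_mlr(y, demo_m)
        np.testing.assert_allclose(
            a.betas.to_numpy(), b.betas.to_numpy(), atol=1e-9
        )

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(3)
        demo = _demo(rng, 50)
        demo["mass"] = 2.0 * demo["height"]
        with pytest.raises(ValueError, match="collinear"):
            standardized_mlr(rng.normal(size=50), demo)

    def test_significance_stars(self):
        rng = np.random.default_rng(4)
        demo = _demo(rng, 120)
        h = demo["height"].to_numpy()
        y = h + rng.normal(0, 2, 120)
        res = standardized_mlr(y, demo)
        assert res.significance("height") == "**"

    def test_regression_table_shape(self):
        rng = np.random.default_rng(5)
        demo = _demo(rng, 60)
        scores = rng.normal(size=(60, 3))
        table = regression_table(scores, demo)
        assert list(table.columns) == ["mode1", "mode2", "mode3"]
        assert "R2" in table.index and "p_age" in table.index

    def test_estimator_interface(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 40)
        est = StandardizedLinearModel().fit(X, y)
        assert est.coef_.shape == (2,)
        assert est.get_params()["max_condition"] == 1e8


class TestForwardStepwise:
    def test_single_informative_mode_selected(self):
        rng = np.random.default_rng(7)
        n = 100
        sex = np.repeat([0, 1], n // 2)
        scores = rng.normal(size=(n, 5))
        scores[:, 2] += 1.5 * sex  # class means 1.5 SD apart on mode 3
        sel, clf = forward_stepwise_logistic(scores, sex)
        assert sel == [2]
        assert clf.coef_.shape == (1,)

    def test_two_informative_modes_selected_first(self):
        rng = np.random.default_rng(8)
        n = 120
        sex = np.repeat([0, 1], n // 2)
        scores = rng.normal(size=(n, 3))
        scores[:, 0] += 1.2 * sex
        scores[:, 1] -= 1.0 * sex
        sel, _ = forward_stepwise_logistic(scores, sex)
        assert set(sel) >= {0, 1}
        assert sel[0] in (0, 1) and sel[1] in (0, 1)

    def test_shuffled_labels_mostly_select_nothing(self):
        """Label permutation null: with five candidate modes the chance that
        the smallest of ~5 near-uniform LRT p-values clears alpha = 0.05 is
        roughly 1 - 0.95^5, so an empty selection is expected in roughly
        three quarters of replicates; require at least 70% over 50 seeded
        replicates."""
        rng = np.random.default_rng(9)
        n = 100
        empty = 0
        for _ in range(50):
            scores = rng.normal(size=(n, 5))
            sex = rng.permutation(np.repeat([0, 1], n // 2))
            sel, _ = forward_stepwise_logistic(scores, sex)
            empty += len(sel) == 0
        assert empty >= 35

    def test_selected_modes_all_significant(self):
        from kneessfm.stats import _fit_logit
        from scipy.stats import chi2

        rng = np.random.default_rng(10)
        n = 150
        sex = np.repeat([0, 1], n // 2)
        scores = rng.normal(size=(n, 4))
        scores[:, 0] += 1.0 * sex
        scores[:, 3] += 0.8 * sex
        sel, clf = forward_stepwise_logistic(scores, sex)
        # removing any selected mode from the final model loses significant fit
        _, _, llf_full, _ = _fit_logit(scores[:, sel], sex)
        for drop in sel:
            rest = [j for j in sel if j != drop]
            if rest:
                _, _, llf0, _ = _fit_logit(scores[:, rest], sex)
            else:
                from kneessfm.stats import _null_llf

                llf0 = _null_llf(sex.astype(float))
            p = chi2.sf(2 * (llf_full - llf0), df=1)
            assert p < 0.05

    def test_perfect_separation_falls_back_to_penalised(self, caplog):
        scores = np.linspace(-2, 2, 40).reshape(-1, 1)
        sex = (scores[:, 0] > 0).astype(float)
        with caplog.at_level("WARNING"):
            clf = StepwiseSexClassifier().fit(scores, sex)
        assert clf.selected_ == [0]
        assert clf.penalized_
        assert np.all(clf.predict(scores) == sex)

    def test_label_validation(self):
        with pytest.raises(ValueError, match="0/1"):
            StepwiseSexClassifier().fit(np.zeros((10, 2)), np.arange(10))
        with pytest.raises(ValueError, match="both classes"):
            StepwiseSexClassifier().fit(np.zeros((10, 2)), np.zeros(10))


class TestStratifiedCV:
    def test_separable_data_perfect_metrics(self):
        rng = np.random.default_rng(11)
        n = 60
        sex = np.repeat([0, 1], n // 2)
        scores = rng.normal(size=(n, 1)) * 0.3 + 5.0 * sex[:, None]
        out = stratified_cv(scores, sex, folds=10, seed=0)
        assert out["accuracy"] == 1.0
        assert out["auc"] == 1.0
        assert out["ci95"][0] <= out["accuracy"] <= out["ci95"][1]

    def test_null_accuracy_within_binomial_band(self):
        rng = np.random.default_rng(12)
        n = 200
        sex = rng.permutation(np.repeat([0, 1], n // 2))
        scores = rng.normal(size=(n, 2))
        out = stratified_cv(scores, sex, folds=10, seed=1)
        assert 0.35 <= out["accuracy"] <= 0.65

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        n = 60
        sex = np.repeat([0, 1], n // 2)
        scores = rng.normal(size=(n, 2)) + sex[:, None]
        a = stratified_cv(scores, sex, seed=42)
        b = stratified_cv(scores, sex, seed=42)
        assert a["accuracy"] == b["accuracy"] and a["auc"] == b["auc"]
        pd.testing.assert_frame_equal(a["folds"], b["folds"])

    def test_folds_preserve_class_proportions(self):
        rng = np.random.default_rng(14)
        n = 100
        sex = np.repeat([0, 1], [60, 40])
        scores = rng.normal(size=(n, 2))
        out = stratified_cv(scores, sex, folds=10, seed=3)
        by_fold = out["folds"].groupby("fold")["sex"].mean()
        assert np.allclose(by_fold, 0.4, atol=1e-9)

    def test_small_class_rejected(self):
        sex = np.repeat([0, 1], [5, 55])
        with pytest.raises(ValueError, match="fold count"):
            stratified_cv(np.zeros((60, 1)), sex, folds=10)

    def test_cv_accuracy_close_to_training_on_separable_data(self):
        rng = np.random.default_rng(15)
        n = 80
        sex = np.repeat([0, 1], n // 2)
        scores = rng.normal(size=(n, 2))
        scores[:, 0] += 2.5 * sex
        clf = StepwiseSexClassifier().fit(scores, sex)
        train_acc = float(np.mean(clf.predict(scores) == sex))
        cv = stratified_cv(scores[:, clf.selected_], sex, seed=0)
        assert cv["accuracy"] >= train_acc - 0.1


def _cp_bisect(successes, n, level=0.95):
    """Independent oracle: invert the exact binomial tails by bisection."""
    alpha = (1 - level) / 2

    def solve(fn, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if fn(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if successes == 0 else solve(
        lambda p: binom.sf(successes - 1, n, p) < alpha, 0.0, 1.0
    )
    upper = 1.0 if successes == n else solve(
        lambda p: binom.cdf(successes, n, p) >= alpha, 0.0, 1.0
    )
    return lower, upper


class TestBinomialCI:
    def test_boundaries(self):
        assert binomial_ci_exact(0, 10)[0] == 0.0
        assert binomial_ci_exact(10, 10)[1] == 1.0

    def test_printed_interval_for_47_of_51(self):
        lo, hi = binomial_ci_exact(47, 51)
        assert round(100 * lo, 1) == 81.1
        assert round(100 * hi, 1) == 97.8
        blo, bhi = _cp_bisect(47, 51)
        assert abs(lo - blo) < 1e-6 and abs(hi - bhi) < 1e-6

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(1, 100), st.data())
    def test_matches_bisection_oracle(self, n, data):
        successes = data.draw(st.integers(0, n))
        lo, hi = binomial_ci_exact(successes, n)
        blo, bhi = _cp_bisect(successes, n)
        assert abs(lo - blo) < 1e-6
        assert abs(hi - bhi) < 1e-6

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            binomial_ci_exact(11, 10)


class TestDecisionGeometry:
    def _clf(self, coef, intercept, selected):
        clf = StepwiseSexClassifier()
        clf.coef_ = np.asarray(coef, float)
        clf.intercept_ = float(intercept)
        clf.selected_ = selected
        return clf

    def test_axis_aligned_plane(self):
        rng = np.random.default_rng(16)
        scores = rng.normal(size=(20, 3))
        sex = (rng.random(20) < 0.5).astype(float)
        sex[0], sex[1] = 0, 1  # both classes present
        geom = decision_geometry(self._clf([1, 0, 0], 0.0, [0, 1, 2]), scores, sex)
        np.testing.assert_allclose(geom["normal"], [1, 0, 0])
        assert geom["offset"] == 0.0

    def test_axis_parallel_to_separating_mode(self):
        rng = np.random.default_rng(17)
        n = 400
        sex = np.repeat([0.0, 1.0], n // 2)
        scores = rng.normal(size=(n, 2)) * 0.2
        scores[:, 0] += np.where(sex == 1, 1.0, -1.0)
        clf = StepwiseSexClassifier().fit(scores, sex)
        geom = decision_geometry(clf, scores, sex)
        axis = geom["male_female_axis"]
        axis = axis / np.linalg.norm(axis)
        # the male-female axis aligns with the separating mode's direction
        lead = np.zeros_like(axis)
        lead[clf.selected_.index(0)] = 1.0
        assert abs(axis @ lead) > 0.99

    def test_translation_shifts_offset_not_normal(self):
        rng = np.random.default_rng(18)
        n = 100
        sex = np.repeat([0.0, 1.0], n // 2)
        scores = rng.normal(size=(n, 2))
        scores[:, 0] += 1.5 * sex
        clf = StepwiseSexClassifier().fit(scores, sex)
        g0 = decision_geometry(clf, scores, sex)
        shifted = scores + 5.0
        clf2 = StepwiseSexClassifier().fit(shifted, sex)
        g1 = decision_geometry(clf2, shifted, sex)
        np.testing.assert_allclose(
            np.abs(g0["normal"]), np.abs(g1["normal"]), atol=0.2
        )
        assert abs(g1["offset"] - g0["offset"]) > 1.0

    def test_zero_coefficients_rejected(self):
        with pytest.raises(ValueError, match="coefficients"):
            decision_geometry(
                self._clf(np.zeros(2), 0.0, [0, 1]), np.zeros((4, 2)), np.array([0, 0, 1, 1])
            )
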