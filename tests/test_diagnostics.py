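import math

import numpy as np
import pandas as pd
import pytest

from allergoscope.diagnostics import (
    best_subsets,
    cross_validated_auc,
    logistic_fit,
    panel_evaluation,
    roc_auc,
    trapezoid_auc,
)
from allergoscope.simulate import generate_cohort

from .oracles import auc_oracle


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_interleaved_example(self):
        # positives {2,4}, negatives {1,3}: 3 of 4 pairs concordant
        res = roc_auc([2, 4, 1, 3], [1, 1, 0, 0])
        assert res.auc == 0.75

    def test_all_tied_scores(self):
        res = roc_auc([5, 5, 5, 5], [1, 0, 1, 0])
        assert res.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_rank_statistic_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 60)
        scores = rng.integers(0, 10, size=n).astype(float)  # ties guaranteed
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(auc_oracle(scores, labels), abs=1e-12)
        assert trapezoid_auc(res) == pytest.approx(res.auc, abs=1e-12)

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(1)
        res = roc_auc(rng.normal(size=100), rng.integers(0, 2, size=100))
        assert (np.diff(res.sensitivity) >= -1e-12).all()
        assert (np.diff(1.0 - res.specificity) >= -1e-12).all()


class TestLogisticFit:
    def test_saturated_two_by_two_closed_form(self):
        # counts (a,b;c,d) = (30,10;10,30): slope = ln(ad/bc) = ln 9
        x = np.r_[np.ones(40), np.zeros(40)]
        y = np.r_[np.ones(30), np.zeros(10), np.ones(10), np.zeros(30)]
        fit = logistic_fit(x, y)
        assert fit.converged
        assert fit.coefficients[1] == pytest.approx(math.log(9), abs=1e-6)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(10)
        n = 5000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-1.0 + 1.5 * x)))
        y = (rng.random(n) < p).astype(int)
        fit = logistic_fit(x, y)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(-1.0, abs=0.15)
        assert fit.coefficients[1] == pytest.approx(1.5, abs=0.15)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        y = (rng.random(200) < 0.4).astype(int)
        fit = logistic_fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)
        assert fit.aic == pytest.approx(ref.aic, abs=1e-5)
        np.testing.assert_allclose(fit.coefficients, ref.params.to_numpy(), atol=1e-5)

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.warns(UserWarning, match="separation"):
            fit = logistic_fit(x, y)
        assert not fit.converged

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_fit(np.arange(10.0), np.ones(10))

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = (rng.random(50) < 0.5).astype(int)
        y[0], y[1] = 0, 1
        with pytest.raises(ValueError, match="b"):
            logistic_fit(X, y)

    def test_null_model_aic(self):
        n = 40
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        fit = logistic_fit(np.empty((n, 0)), y)
        assert fit.aic == pytest.approx(2 - 2 * n * math.log(0.5), abs=1e-8)


class TestBestSubsets:
    def _informative_design(self, seed, n=1000):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["info", "noise1", "noise2"])
        p = 1 / (1 + np.exp(-(2.0 * X["info"].to_numpy())))
        y = (rng.random(n) < p).astype(int)
        return X, y

    def test_informative_predictor_selected_first(self):
        X, y = self._informative_design(0)
        traj = best_subsets(X, y)
        assert traj.best_subsets[0] == ("info",)
        assert traj.sizes == [1, 2, 3]

    def test_aic_of_best_subset_improves_then_penalises(self):
        X, y = self._informative_design(1)
        traj = best_subsets(X, y)
        assert traj.aics[0] < logistic_fit(X[["noise1"]], y).aic

    def test_column_order_invariance(self):
        X, y = self._informative_design(2)
        t1 = best_subsets(X, y)
        t2 = best_subsets(X[["noise2", "info", "noise1"]], y)
        assert t1.best_subsets == t2.best_subsets
        assert t1.aics == pytest.approx(t2.aics)

    def test_duplicate_predictor_rejected(self):
        X, y = self._informative_design(3)
        X = X.assign(dup=X["info"])
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            best_subsets(X, y)

    def test_too_many_predictors_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(40, 16)))
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        with pytest.raises(ValueError, match="screen"):
            best_subsets(X, y)


@pytest.fixture(scope="module")
def cohort():
    # a large challenged arm: with strong within-group titre correlation
    # a proxy analyte can outrank the target by sampling noise in small
    # arms, so the identifiability property is checked at high power
    cohort, _ = generate_cohort(
        n_subjects=400, ofc_counts={"grass_carp": 400, "salmon": 400}, seed=21
    )
    return cohort


class TestPanelEvaluation:
    def test_target_extract_attains_best_single_auc(self, cohort):
        report = panel_evaluation(cohort, "grass_carp", max_size=3)
        assert report.single_auc.iloc[0]["analyte"] == "grass_carp"
        assert report.target_auc == report.single_auc["auc"].max()

    def test_in_sample_auc_never_drops_with_more_predictors(self, cohort):
        report = panel_evaluation(cohort, "grass_carp", max_size=4)
        # the full-size in-sample AUC dominates the size-1 AUC
        assert max(report.with_target.aucs) >= report.with_target.aucs[0] - 1e-12

    def test_without_target_excludes_target_analyte(self, cohort):
        report = panel_evaluation(cohort, "salmon", max_size=3)
        for subset in report.without_target.best_subsets:
            assert "salmon" not in subset

    def test_shuffled_labels_give_chance_auc(self):
        cohort, _ = generate_cohort(n_subjects=200, ofc_counts={"grass_carp": 200, "salmon": 0}, seed=22)
        rng = np.random.default_rng(23)
        shuffled = cohort.ofc["grass_carp"].to_numpy().copy()
        rng.shuffle(shuffled)
        cohort.ofc["grass_carp"] = shuffled
        report = panel_evaluation(cohort, "grass_carp", max_size=1)
        assert report.target_auc == pytest.approx(0.5, abs=0.08)

    def test_missing_ofc_fish_rejected(self, cohort):
        with pytest.raises(KeyError):
            panel_evaluation(cohort, "tilapia")

    def test_cross_validated_auc_below_in_sample(self, cohort):
        labelled = cohort.ofc["grass_carp"].isin(["allergic", "tolerant"])
        X = np.log10(cohort.sige.loc[labelled] + 0.01)
        y = (cohort.ofc.loc[labelled, "grass_carp"] == "allergic").to_numpy().astype(int)
        fit = logistic_fit(X, y)
        in_sample = roc_auc(fit.fitted, y).auc
        cv = cross_validated_auc(X, y, seed=1)
        assert 0.4 < cv <= in_sample + 0.05
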