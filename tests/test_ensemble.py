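"""Logistic fits, stepwise AIC, Hosmer–Lemeshow gate, ROC/AUC, ensemble."""

import numpy as np
import pytest
from scipy import special
from sklearn.metrics import roc_auc_score

from ashazard import (
    fit_logistic,
    hosmer_lemeshow,
    predict_prob,
    roc_auc,
    run_ensemble,
    select_final,
    stepwise_aic,
)
from ashazard.ensemble import (
    CombinationStats,
    EnsembleSummary,
    FittedModel,
    UndefinedAUCError,
)
from tests.test_screening import make_dataset


def brute_force_auc(scores, y):
    """Pairwise concordance: P(random positive outscores random negative)."""
    pos = np.asarray(scores)[np.asarray(y) == 1]
    neg = np.asarray(scores)[np.asarray(y) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(25), np.zeros(75)]
        m = fit_logistic(np.empty((100, 0)), y, variables=())
        assert m.intercept == pytest.approx(np.log(0.25 / 0.75), abs=1e-6)
        assert m.aic == pytest.approx(2 - 2 * m.log_likelihood)

    def test_parameter_recovery(self, rng):
        n = 5000
        X = rng.normal(size=(n, 3))
        beta = np.array([0.8, -0.5, 0.3])
        y = (rng.random(n) < special.expit(-1.0 + X @ beta)).astype(float)
        m = fit_logistic(X, y)
        # asymptotic SEs from the inverse information at the truth
        p = special.expit(-1.0 + X @ beta)
        design = np.column_stack([np.ones(n), X])
        info = (design * (p * (1 - p))[:, None]).T @ design
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        est = np.r_[m.intercept, m.coefficients]
        assert np.all(np.abs(est - np.r_[-1.0, beta]) < 3 * se)

    def test_collinear_covariate_flagged(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        m = fit_logistic(np.zeros((40, 1)), y)  # constant column, singular
        assert not m.converged

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(300, 2))
        y = (rng.random(300) < special.expit(X[:, 0])).astype(float)
        m = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            np.r_[m.intercept, m.coefficients], ref.params, atol=1e-6
        )
        assert m.log_likelihood == pytest.approx(ref.llf, abs=1e-8)


class TestPredictProb:
    def test_null_model_half(self):
        m = FittedModel(("a", "b"), 0.0, np.zeros(2), 0.0, True)
        assert predict_prob(m, np.zeros(2)) == pytest.approx(0.5)

    def test_published_style_model_at_feature_means(self):
        """Intercept −1.75 with all-zero normalized inputs → 1/(1+e^1.75)."""
        m = FittedModel(
            ("pet", "slope", "swc"),
            -1.75,
            np.array([3.47, -25.19, -3.55]),
            0.0,
            True,
        )
        p = predict_prob(m, np.zeros(3))
        assert p == pytest.approx(1.0 / (1.0 + np.exp(1.75)), abs=1e-6)
        assert p == pytest.approx(0.1480, abs=5e-5)

    def test_odds_identity(self, rng):
        m = FittedModel(("a", "b"), 0.3, np.array([1.2, -0.7]), 0.0, True)
        x = rng.normal(size=(20, 2))
        p = predict_prob(m, x)
        np.testing.assert_allclose(
            p / (1 - p), np.exp(m.linear_predictor(x)), rtol=1e-12
        )

    def test_name_mismatch_rejected(self):
        m = FittedModel(("a",), 0.0, np.zeros(1), 0.0, True)
        with pytest.raises(KeyError):
            predict_prob(m, np.zeros(1), variables=("b",))


@pytest.fixture(scope="module")
def signal_data():
    rng = np.random.default_rng(10)
    n = 2000
    X = rng.normal(size=(n, 10))
    y = (rng.random(n) < special.expit(-1.0 + 1.5 * X[:, 0])).astype(int)
    return X, y, [f"v{i}" for i in range(10)]


@pytest.fixture(scope="module")
def small_dataset():
    rng = np.random.default_rng(21)
    n = 600
    X = rng.normal(size=(n, 4))
    y = (rng.random(n) < special.expit(-1.0 + 1.2 * X[:, 0] - 0.8 * X[:, 1])).astype(int)
    return make_dataset(X, y, ("a", "b", "c", "d"))


class TestStepwiseAic:
    def test_true_predictor_selected(self, signal_data):
        """One real predictor among nine noise: kept in ≥95% of replicates."""
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            X = rng.normal(size=(600, 10))
            y = (rng.random(600) < special.expit(-1.0 + 1.5 * X[:, 0])).astype(int)
            m = stepwise_aic(X, y, [f"v{i}" for i in range(10)])
            hits += "v0" in m.variables
        assert hits >= 95

    def test_singleton_set_reduction(self, signal_data):
        X, y, _ = signal_data
        m = stepwise_aic(X[:, :1], y, ["v0"])
        assert m.variables in ((), ("v0",))
        assert m.variables == ("v0",)  # strong signal wins over null

    def test_termination_is_local_optimum(self, signal_data):
        X, y, names = signal_data
        m = stepwise_aic(X, y, names)
        sel = set(m.variables)
        col = {v: i for i, v in enumerate(names)}

        def aic_of(combo):
            cols = [col[v] for v in sorted(combo)]
            return fit_logistic(X[:, cols], y, tuple(sorted(combo))).aic

        base = aic_of(sel)
        for v in names:
            neighbor = sel - {v} if v in sel else sel | {v}
            assert base <= aic_of(neighbor) + 1e-9

    def test_deterministic(self, signal_data):
        X, y, names = signal_data
        assert stepwise_aic(X, y, names).variables == stepwise_aic(X, y, names).variables


class TestHosmerLemeshow:
    def test_perfect_calibration_statistic_zero(self):
        probs = np.full(40, 0.5)
        y = np.tile([0, 1], 20)
        stat, p = hosmer_lemeshow(probs, y)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_gross_misfit_rejected(self):
        y = np.tile([0, 1], 50)
        probs = 1.0 - y * 0.98 - 0.01  # anti-correlated
        _, p = hosmer_lemeshow(probs, y)
        assert p < 0.05

    def test_degenerate_group_warns(self):
        probs = np.r_[np.zeros(20), np.linspace(0.3, 0.9, 20)]
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        with pytest.warns(UserWarning, match="degenerate"):
            hosmer_lemeshow(probs, y)

    def test_type_i_error_calibrated(self, rng):
        """Rejection rate ≈ 5% when the model is correctly specified."""
        n, n_sims, rejections = 500, 400, 0
        X = rng.normal(size=(n, 2))
        eta = -0.5 + X @ np.array([1.0, -0.7])
        p_true = special.expit(eta)
        for _ in range(n_sims):
            y = (rng.random(n) < p_true).astype(float)
            m = fit_logistic(X, y)
            probs = special.expit(m.linear_predictor(X))
            _, p = hosmer_lemeshow(probs, y)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sims <= 0.08


class TestRocAuc:
    def test_worked_example(self):
        curve = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, 10000)
        y[:2] = [0, 1]
        auc = roc_auc(rng.random(10000), y).auc
        assert abs(auc - 0.5) < 0.02

    def test_matches_concordance_and_sklearn(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            scores = np.round(rng.random(n), 2)  # force ties
            curve = roc_auc(scores, y)
            assert curve.auc == pytest.approx(brute_force_auc(scores, y), abs=1e-9)
            assert curve.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-9)

    def test_curve_monotone(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        curve = roc_auc(rng.random(200), y)
        assert np.all(np.diff(curve.sensitivity) <= 0)
        assert np.all(np.diff(curve.specificity) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([0.1, 0.2], [1, 1])


class TestRunEnsemble:
    def test_single_run(self, small_dataset):
        summ = run_ensemble(small_dataset, 1.0, ["a", "b", "c", "d"],
                            n_runs=1, base_seed=0)
        assert summ.n_runs == 1
        if summ.combinations:
            assert len(summ.combinations) == 1
            assert summ.combinations[0].count == 1

    def test_counts_sum_to_passed(self, small_dataset):
        summ = run_ensemble(small_dataset, 1.0, ["a", "b", "c", "d"],
                            n_runs=40, base_seed=1)
        assert sum(c.count for c in summ.combinations) == summ.n_passed
        assert all(c.coef_sd.min() >= 0 for c in summ.combinations)

    def test_deterministic(self, small_dataset):
        a = run_ensemble(small_dataset, 1.0, ["a", "b"], n_runs=20, base_seed=5)
        b = run_ensemble(small_dataset, 1.0, ["a", "b"], n_runs=20, base_seed=5)
        assert (a.n_passed, a.n_diverged) == (b.n_passed, b.n_diverged)
        assert a.as_frame().equals(b.as_frame())
        for ca, cb in zip(a.combinations, b.combinations):
            assert ca.variables == cb.variables
            np.testing.assert_array_equal(ca.coef_mean, cb.coef_mean)

    def test_hl_pass_fraction_well_specified(self, small_dataset):
        """Well-specified model: HL pass fraction ≈ 1 − α."""
        summ = run_ensemble(small_dataset, 1.0, ["a", "b"], n_runs=200, base_seed=2)
        rate = summ.n_passed / summ.n_runs
        assert rate > 0.85

    def test_coefficients_near_full_data_fit(self, small_dataset):
        """Averaged coefficients approach the full-data fit for large trains."""
        summ = run_ensemble(small_dataset, 1.0, ["a", "b"], n_runs=50,
                            base_seed=3, train_fraction=0.95, hl_groups=5)
        full = fit_logistic(small_dataset.columns(["a", "b"]),
                            small_dataset.labels[1.0], ("a", "b"))
        combo = max(summ.combinations, key=lambda c: c.count)
        assert combo.variables == ("a", "b")
        np.testing.assert_allclose(combo.coef_mean, full.coefficients, atol=0.15)


class TestSelectFinal:
    def make_combo(self, names, auc, count=10):
        k = len(names)
        return CombinationStats(tuple(names), count, 0.0, 0.0,
                                np.zeros(k), np.zeros(k), auc, auc)

    def summary(self, combos):
        return EnsembleSummary(10.0, 100, sum(c.count for c in combos),
                               0, tuple(combos))

    def test_highest_auc_wins(self):
        s = self.summary([self.make_combo(["a", "b", "c"], 0.83),
                          self.make_combo(["d", "e", "f"], 0.79)])
        assert select_final(s).variables == ("a", "b", "c")

    def test_single_combination_identity(self):
        s = self.summary([self.make_combo(["a"], 0.7, count=3)])
        fm = select_final(s)
        assert fm.variables == ("a",) and fm.count == 3

    def test_tie_broken_by_count(self):
        s = self.summary([self.make_combo(["a"], 0.8, count=100),
                          self.make_combo(["b"], 0.8, count=400)])
        assert select_final(s).variables == ("b",)

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            select_final(EnsembleSummary(10.0, 10, 0, 0, ()))
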