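"""Elastic-net multinomial fit, tuning, probability calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import softmax

from methylancestry.classifier import (
    ElasticNetEthnicityClassifier,
    HyperparameterGrid,
    PipelineConfig,
    call_ethnicity,
    desk_scale_config,
    fit_elastic_net_multinomial,
    fit_pipeline,
    predict_probabilities,
    tune_hyperparameters,
)
from methylancestry.io import AMBIGUOUS, CLASSES, FittedClassifier
from methylancestry.preprocess import PreprocessConfig


def bruteforce_objective_minimum(X, y, alpha, lam):
    """Independent convex solve of the penalized multinomial objective.

    The L1 term is made smooth by splitting coefficients into positive and
    negative parts with non-negativity bounds, then L-BFGS-B minimizes the
    exact objective.
    """
    classes = np.unique(y)
    K, (n, p) = len(classes), X.shape
    Y = (y[:, None] == classes[None, :]).astype(float)

    def f(z):
        b0 = z[:K]
        wp = z[K : K + K * p].reshape(K, p)
        wn = z[K + K * p :].reshape(K, p)
        W = wp - wn
        eta = X @ W.T + b0
        P = softmax(eta, axis=1)
        idx = np.searchsorted(classes, y)
        nll = -np.mean(np.log(np.clip(P[np.arange(n), idx], 1e-300, None)))
        return nll + lam * ((1 - alpha) / 2 * (W**2).sum() + alpha * (wp + wn).sum())

    z0 = np.zeros(K + 2 * K * p)
    bounds = [(None, None)] * K + [(0, None)] * (2 * K * p)
    res = minimize(
        f, z0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 50_000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return res.fun


def _fixture_30x5(seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(30, 5))
    y = np.array(list(CLASSES) * 10, dtype=object)
    X[y == "Asian"] += 0.8
    X[y == "Caucasian"] -= 0.5
    return X, y


class TestSolver:
    def test_objective_matches_bruteforce_minimum(self):
        X, y = _fixture_30x5()
        est = ElasticNetEthnicityClassifier(
            alpha=0.5, lam=0.05, standardize=False, tol=1e-12, max_iter=50_000
        ).fit(X, y)
        oracle = bruteforce_objective_minimum(X, y, 0.5, 0.05)
        assert est.objective(X, y) == pytest.approx(oracle, abs=1e-4)

    def test_huge_penalty_recovers_empirical_priors(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 3))
        y = np.array(["African", "African", "Asian", "Caucasian"], dtype=object)
        est = ElasticNetEthnicityClassifier(alpha=0.5, lam=1e3, tol=1e-14, max_iter=20_000)
        est.fit(X, y)
        probs = est.predict_proba(X)
        np.testing.assert_allclose(probs, np.tile([0.5, 0.25, 0.25], (4, 1)), atol=1e-6)
        assert not est.selected_mask().any()

    def test_unpenalized_fit_matches_mnlogit(self):
        # lam=0 must agree with a standard unpenalized multinomial fit
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 60
        X = rng.normal(size=(n, 2))
        logits = np.column_stack([X[:, 0], X[:, 1], -0.3 * X[:, 0]])
        y_idx = np.array([rng.choice(3, p=softmax(l)) for l in logits])
        y = np.asarray(CLASSES, dtype=object)[y_idx]

        est = ElasticNetEthnicityClassifier(
            alpha=0.5, lam=0.0, standardize=False, tol=1e-12, max_iter=100_000
        ).fit(X, y)
        ref = sm.MNLogit(y_idx, sm.add_constant(X)).fit(disp=0, method="newton")
        # statsmodels uses class 0 as reference; compare in that parameterization
        ours = np.column_stack(
            [
                np.concatenate([[est.intercept_[k] - est.intercept_[0]],
                                est.coef_[k] - est.coef_[0]])
                for k in (1, 2)
            ]
        )
        np.testing.assert_allclose(ours, ref.params, atol=1e-3)

    def test_objective_non_increasing_in_lambda_site_count(self):
        X, y = _fixture_30x5(3)
        counts = []
        for lam in (0.001, 0.01, 0.05, 0.2, 1.0):
            est = ElasticNetEthnicityClassifier(alpha=0.5, lam=lam, tol=1e-10,
                                                max_iter=20_000).fit(X, y)
            counts.append(int(est.selected_mask().sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nonfinite_input_rejected(self):
        X, y = _fixture_30x5()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            ElasticNetEthnicityClassifier().fit(X, y)

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="2 classes"):
            ElasticNetEthnicityClassifier().fit(X, np.array(["Asian"] * 4))


class TestPrediction:
    def test_hand_softmax_single_site(self):
        model = FittedClassifier(
            classes=list(CLASSES),
            intercepts=np.zeros(3),
            coefficients=np.array([[2.0], [0.0], [-2.0]]),
            model_sites=["cg1"],
            alpha=0.5,
            lam=0.1,
        )
        beta = pd.DataFrame([[0.5]], index=["cg1"], columns=["S0"])
        probs = predict_probabilities(model, beta)
        np.testing.assert_allclose(
            probs.to_numpy()[0], [0.66524096, 0.24472847, 0.09003057], atol=1e-6
        )

    def test_site_order_irrelevant(self):
        rng = np.random.default_rng(4)
        model = FittedClassifier(
            classes=list(CLASSES),
            intercepts=rng.normal(size=3),
            coefficients=rng.normal(size=(3, 4)),
            model_sites=[f"cg{i}" for i in range(4)],
            alpha=0.5,
            lam=0.1,
        )
        beta = pd.DataFrame(
            rng.uniform(size=(4, 3)), index=model.model_sites, columns=list("ABC")
        )
        shuffled = beta.iloc[[2, 0, 3, 1]]
        np.testing.assert_array_equal(
            predict_probabilities(model, beta).to_numpy(),
            predict_probabilities(model, shuffled).to_numpy(),
        )

    def test_missing_model_sites_listed(self):
        model = FittedClassifier(
            classes=list(CLASSES), intercepts=np.zeros(3),
            coefficients=np.zeros((3, 2)), model_sites=["cg1", "cg2"],
            alpha=0.5, lam=0.1,
        )
        beta = pd.DataFrame([[0.5]], index=["cg1"], columns=["S0"])
        with pytest.raises(KeyError, match="cg2"):
            predict_probabilities(model, beta)

    def test_probability_shift_invariance(self):
        # adding a constant to every class linear predictor leaves probs unchanged
        rng = np.random.default_rng(5)
        coefs = rng.normal(size=(3, 2))
        intercepts = rng.normal(size=3)
        beta = pd.DataFrame(rng.uniform(size=(2, 5)), index=["cg1", "cg2"])
        m1 = FittedClassifier(list(CLASSES), intercepts, coefs, ["cg1", "cg2"], 0.5, 0.1)
        m2 = FittedClassifier(list(CLASSES), intercepts + 7.3, coefs, ["cg1", "cg2"], 0.5, 0.1)
        np.testing.assert_allclose(
            predict_probabilities(m1, beta).to_numpy(),
            predict_probabilities(m2, beta).to_numpy(),
            atol=1e-12,
        )


class TestCalls:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ((0.80, 0.10, 0.10), "African"),
            ((0.50, 0.30, 0.20), AMBIGUOUS),
            ((0.75, 0.15, 0.10), "African"),  # exactly at threshold is called
            ((0.10, 0.76, 0.14), "Asian"),
        ],
    )
    def test_threshold_semantics(self, probs, expected):
        frame = pd.DataFrame([probs], columns=list(CLASSES), index=["S0"])
        (result,) = call_ethnicity(frame, threshold=0.75)
        assert result.predicted == expected

    def test_bad_probability_sum_rejected(self):
        frame = pd.DataFrame([[0.5, 0.4, 0.2]], columns=list(CLASSES), index=["S0"])
        with pytest.raises(ValueError, match="sum"):
            call_ethnicity(frame)

    @given(
        a=st.floats(0.0, 1.0), b=st.floats(0.0, 1.0),
        t=st.floats(0.3, 0.99),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_ambiguous_iff_max_below_threshold(self, a, b, t):
        raw = np.array([a, b, 1.0]) + 1e-9
        p = raw / raw.sum()
        frame = pd.DataFrame([p], columns=list(CLASSES), index=["S0"])
        (result,) = call_ethnicity(frame, threshold=t)
        assert (result.predicted == AMBIGUOUS) == (p.max() < t)


class TestTuning:
    def test_single_point_grid_returned(self):
        X, y = _fixture_30x5(6)
        grid = HyperparameterGrid(alphas=(0.3,), lambdas=(0.02,), cv_folds=3, cv_repeats=1)
        a, l, table = tune_hyperparameters(X, y, grid, seed=0)
        assert (a, l) == (0.3, 0.02)
        assert len(table) == 1

    def test_signal_beats_intercept_only_model(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 4))
        y = np.asarray(CLASSES, dtype=object)[np.arange(60) % 3]
        X[y == "Asian", 0] += 3
        X[y == "Caucasian", 1] += 3
        grid = HyperparameterGrid(
            alphas=(0.5,), lambdas=(0.001, 1e3), cv_folds=3, cv_repeats=1
        )
        _, best_lam, table = tune_hyperparameters(X, y, grid, seed=0)
        assert best_lam == 0.001
        losses = table.set_index("lambda")["logLoss"]
        assert losses[0.001] < losses[1e3]

    def test_same_seed_identical_cv_table(self):
        X, y = _fixture_30x5(8)
        grid = HyperparameterGrid(alphas=(0.2, 0.5), lambdas=(0.01, 0.1),
                                  cv_folds=3, cv_repeats=2)
        _, _, t1 = tune_hyperparameters(X, y, grid, seed=42)
        _, _, t2 = tune_hyperparameters(X, y, grid, seed=42)
        pd.testing.assert_frame_equal(t1, t2)

    def test_class_smaller_than_folds_rejected(self):
        X, y = _fixture_30x5()
        grid = HyperparameterGrid(alphas=(0.5,), lambdas=(0.1,), cv_folds=20)
        with pytest.raises(ValueError, match="folds"):
            tune_hyperparameters(X, y, grid, seed=0)

    def test_permuted_labels_give_chance_level_cv(self):
        from sklearn.model_selection import cross_val_score

        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 20))
        y = np.asarray(CLASSES, dtype=object)[
            rng.choice(3, size=200, p=[0.25, 0.25, 0.5])
        ]
        X[y == "Asian", 0] += 4  # real signal...
        y_perm = rng.permutation(y)  # ...destroyed by permutation
        est = ElasticNetEthnicityClassifier(alpha=0.5, lam=0.05, tol=1e-6,
                                            max_iter=2000, threshold=0.0)
        acc = cross_val_score(est, X, y_perm, cv=5).mean()
        majority = max(np.mean(y_perm == c) for c in CLASSES)
        assert abs(acc - majority) < 0.05


class TestPipeline:
    def test_end_to_end_selects_sites_and_is_deterministic(self, tiny_sim):
        _, bm, sheet, ann, _ = tiny_sim
        config = PipelineConfig(
            preprocess=PreprocessConfig(bmiq=False),
            grid=HyperparameterGrid(alphas=(0.5,), lambdas=(0.01, 0.1),
                                    cv_folds=3, cv_repeats=1),
        )
        m1 = fit_pipeline(bm, ann, sheet, config, seed=1)
        m2 = fit_pipeline(bm, ann, sheet, config, seed=1)
        assert len(m1.selected_sites) >= 1
        assert m1.selected_sites == m2.selected_sites
        assert any(step.get("step") == "training" for step in m1.preprocessing_record)

    def test_all_missing_labels_rejected(self, tiny_sim):
        _, bm, sheet, ann, _ = tiny_sim
        bad = sheet.data.copy()
        bad["reported_ethnicity"] = np.nan
        from methylancestry.io import SampleSheet

        with pytest.raises(ValueError, match="no labels"):
            fit_pipeline(bm, ann, SampleSheet(bad), desk_scale_config(), seed=0)
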