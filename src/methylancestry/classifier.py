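"""Penalized multinomial ethnicity classifier with ambiguity calls.

The model is multinomial logistic regression with an elastic-net penalty in
the glmnet parameterization: it minimizes

    -(1/N) sum_i log softmax_{y_i}(b0_c + b_c . x_i)
        + lambda * sum_c [ (1-alpha)/2 ||b_c||_2^2 + alpha ||b_c||_1 ]

with unpenalized intercepts and a symmetric softmax over the three classes
(no reference class). Features are standardized internally for fitting and
coefficients are returned on the original beta scale. Samples whose maximum
class probability falls below a confidence threshold (default 0.75) are
called Ambiguous — these are candidates for mixed ancestry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .io import AMBIGUOUS, CLASSES, BetaMatrix, FittedClassifier, PredictionResult, SampleSheet, SiteAnnotation
from .preprocess import PreprocessConfig, run_preprocess

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.75


@dataclass
class HyperparameterGrid:
    """Tuning grid: elastic-net mixing alphas, penalty strengths lambdas."""

    alphas: tuple[float, ...] = tuple(np.geomspace(0.025, 0.5, 6).round(6))
    lambdas: tuple[float, ...] = tuple(np.geomspace(0.0025, 0.25, 8).round(6))
    cv_folds: int = 5
    cv_repeats: int = 3
    selection_metric: str = "logLoss"  # or "accuracy", "kappa"

    def __post_init__(self) -> None:
        if not self.alphas or not self.lambdas:
            raise ValueError("alphas and lambdas must be non-empty")
        if any(a <= 0 or a > 1 for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1]")
        if any(l < 0 for l in self.lambdas):
            raise ValueError("lambdas must be >= 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.selection_metric not in ("logLoss", "accuracy", "kappa"):
            raise ValueError(f"unknown selection metric {self.selection_metric!r}")


def _fit_multinomial_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    classes: np.ndarray,
    alpha: float,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Monotone FISTA solve of the glmnet multinomial elastic-net objective.

    Minimizes -(1/N) sum_i log softmax_{y_i} + lam[(1-alpha)/2 ||W||_F^2 +
    alpha ||W||_1] over symmetric class coefficients W (p x K) and
    unpenalized intercepts. Proximal gradient with Nesterov momentum on the
    smooth part (negative log-likelihood + ridge) and soft-thresholding for
    the L1 part; momentum restarts whenever the objective would rise, so the
    reported objective is non-increasing. Converged when the relative
    objective change drops below ``tol``; ``max_iter`` caps the passes.
    """
    n, p = X.shape
    K = len(classes)
    Y = (y[:, None] == classes[None, :]).astype(float)
    ridge = lam * (1 - alpha)
    l1 = lam * alpha

    # Lipschitz bound for the softmax NLL gradient: 0.5 * smax(Xa)^2 / n,
    # with a column of ones appended for the intercept
    ones = np.ones((n, 1))
    Xa = np.hstack([ones, X])
    gram = Xa @ Xa.T if n <= Xa.shape[1] else Xa.T @ Xa
    smax_sq = float(np.linalg.eigvalsh(gram)[-1])
    L = 0.5 * smax_sq / n + ridge
    step = 1.0 / L

    def objective(b0, W):
        eta = b0 + X @ W
        eta -= eta.max(axis=1, keepdims=True)
        logz = np.log(np.exp(eta).sum(axis=1))
        nll = np.mean(logz - (eta * Y).sum(axis=1))
        return nll + 0.5 * ridge * (W**2).sum() + l1 * np.abs(W).sum()

    def grads(b0, W):
        P = softmax(b0 + X @ W, axis=1)
        R = (P - Y) / n
        return R.sum(axis=0), X.T @ R + ridge * W

    b0 = np.zeros(K)
    W = np.zeros((p, K))
    zb, zW = b0, W  # momentum point
    t = 1.0
    obj = objective(b0, W)
    for _ in range(max_iter):
        g0, G = grads(zb, zW)
        b0_new = zb - step * g0
        W_new = zW - step * G
        if l1 > 0:
            W_new = np.sign(W_new) * np.maximum(np.abs(W_new) - step * l1, 0.0)
        obj_new = objective(b0_new, W_new)
        if obj_new > obj:  # restart momentum; plain proximal step from (b0, W)
            g0, G = grads(b0, W)
            b0_new = b0 - step * g0
            W_new = W - step * G
            if l1 > 0:
                W_new = np.sign(W_new) * np.maximum(np.abs(W_new) - step * l1, 0.0)
            obj_new = objective(b0_new, W_new)
            t = 1.0
        t_new = (1 + np.sqrt(1 + 4 * t**2)) / 2
        zb = b0_new + (t - 1) / t_new * (b0_new - b0)
        zW = W_new + (t - 1) / t_new * (W_new - W)
        done = abs(obj - obj_new) < tol * max(1.0, abs(obj))
        b0, W, t = b0_new, W_new, t_new
        obj = obj_new
        if done:
            break
    # symmetric (sum-to-zero) parameterization: the L1 part makes W unique,
    # but intercepts have a flat direction; centre them
    b0 = b0 - b0.mean()
    return b0, W.T


class ElasticNetEthnicityClassifier(BaseEstimator, ClassifierMixin):
    """Elastic-net multinomial logistic regression in glmnet parameterization.

    Parameters
    ----------
    alpha : float
        Elastic-net mixing in (0, 1]; 1 is pure lasso.
    lam : float
        Penalty strength lambda >= 0; 0 gives the unpenalized fit.
    standardize : bool
        Standardize features internally (training means/SDs only); fitted
        coefficients are always reported on the original input scale.
    threshold : float
        Confidence cutoff for :meth:`predict`; below it, Ambiguous.

    Attributes
    ----------
    classes\\_ : ndarray of class labels (sorted).
    coef\\_ : (n_classes, n_features) coefficients on the input scale.
    intercept\\_ : (n_classes,) intercepts on the input scale.
    """

    def __init__(
        self,
        alpha: float = 0.25,
        lam: float = 0.01,
        standardize: bool = True,
        threshold: float = DEFAULT_THRESHOLD,
        tol: float = 1e-7,
        max_iter: int = 10_000,
    ):
        self.alpha = alpha
        self.lam = lam
        self.standardize = standardize
        self.threshold = threshold
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in X")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to fit")
        if counts.min() < 2:
            small = classes[counts < 2].tolist()
            logger.warning("class(es) with a single sample: %s — fit proceeds but the "
                           "class probability estimates are degenerate", small)
        n = X.shape[0]

        if self.standardize:
            mean = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xs = (X - mean) / sd
        else:
            mean = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
            Xs = X

        intercept_std, coef_std = _fit_multinomial_elastic_net(
            Xs, y, classes, self.alpha, self.lam, tol=self.tol, max_iter=self.max_iter
        )

        self.classes_ = classes
        self.coef_ = coef_std / sd
        self.intercept_ = intercept_std - (coef_std * (mean / sd)).sum(axis=1)
        self.coef_std_ = coef_std
        self.intercept_std_ = intercept_std
        self.feature_mean_ = mean
        self.feature_sd_ = sd
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_.T + self.intercept_

    def predict_proba(self, X):
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X):
        """Thresholded call: argmax class, or Ambiguous below the confidence cutoff."""
        proba = self.predict_proba(X)
        idx = proba.argmax(axis=1)
        calls = self.classes_[idx].astype(object)
        calls[proba.max(axis=1) < self.threshold] = AMBIGUOUS
        return calls

    def selected_mask(self) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return (self.coef_std_ != 0).any(axis=0)

    def objective(self, X, y) -> float:
        """The penalized objective at the fitted solution, on the fitting scale."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        Xs = (X - self.feature_mean_) / self.feature_sd_
        return penalized_objective(
            Xs, np.asarray(y), self.classes_, self.intercept_std_, self.coef_std_,
            self.alpha, self.lam,
        )


def penalized_objective(X, y, classes, intercepts, coefs, alpha, lam) -> float:
    """Evaluate the glmnet-style penalized multinomial objective."""
    y_idx = np.searchsorted(classes, y)
    eta = X @ coefs.T + intercepts
    p = softmax(eta, axis=1)
    nll = -np.mean(np.log(np.clip(p[np.arange(len(y)), y_idx], 1e-300, None)))
    pen = lam * np.sum((1 - alpha) / 2 * (coefs**2).sum(axis=1) + alpha * np.abs(coefs).sum(axis=1))
    return float(nll + pen)


def fit_elastic_net_multinomial(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    site_ids: list[str] | None = None,
    standardize: bool = True,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> FittedClassifier:
    """Fit and package the model as a :class:`FittedClassifier` (beta scale).

    ``X`` is samples x sites in site_ids order.
    """
    est = ElasticNetEthnicityClassifier(
        alpha=alpha, lam=lam, standardize=standardize, tol=tol, max_iter=max_iter
    ).fit(X, y)
    if site_ids is None:
        site_ids = [f"site{i}" for i in range(X.shape[1])]
    classes = list(est.classes_)
    return FittedClassifier(
        classes=classes,
        intercepts=est.intercept_,
        coefficients=est.coef_,
        model_sites=list(site_ids),
        alpha=alpha,
        lam=lam,
    )


def predict_probabilities(model: FittedClassifier, beta: pd.DataFrame) -> pd.DataFrame:
    """Class probabilities for a sites x samples beta frame.

    The frame must contain every model site; extra sites are ignored and
    row order is immaterial.
    """
    missing = [s for s in model.model_sites if s not in beta.index]
    if missing:
        raise KeyError(
            f"{len(missing)} model sites missing from input, first: {missing[:5]}"
        )
    X = beta.loc[model.model_sites].to_numpy().T  # samples x sites
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite beta values at model sites")
    eta = X @ model.coefficients.T + model.intercepts
    probs = softmax(eta, axis=1)
    return pd.DataFrame(probs, index=beta.columns, columns=model.classes)


def call_ethnicity(
    probs: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> list[PredictionResult]:
    """Thresholded calls from a samples x classes probability frame.

    The call is the argmax class when the maximum probability is at or above
    the threshold, else Ambiguous; ties break by fixed class order
    (African < Asian < Caucasian) and are logged.
    """
    probs = probs[list(CLASSES)]
    arr = probs.to_numpy()
    bad = np.abs(arr.sum(axis=1) - 1) > 1e-6
    if bad.any():
        raise ValueError(
            f"probabilities do not sum to 1 for samples: {probs.index[bad].tolist()[:5]}"
        )
    results = []
    for sample, row in zip(probs.index, arr):
        mx = row.max()
        if (row == mx).sum() > 1:
            logger.info("probability tie for sample %s; fixed class order breaks it", sample)
        call = CLASSES[int(row.argmax())] if mx >= threshold else AMBIGUOUS
        results.append(
            PredictionResult(
                sample_id=str(sample),
                prob_african=float(row[0]),
                prob_asian=float(row[1]),
                prob_caucasian=float(row[2]),
                predicted=call,
                threshold=threshold,
            )
        )
    return results


# ---------------------------------------------------------------------------
# tuning


def _metric_value(metric: str, y_true, y_pred, proba, classes) -> float:
    from sklearn.metrics import accuracy_score, cohen_kappa_score

    if metric == "accuracy":
        return accuracy_score(y_true, y_pred)
    if metric == "kappa":
        return cohen_kappa_score(y_true, y_pred)
    # logLoss
    idx = np.searchsorted(classes, y_true)
    p = np.clip(proba[np.arange(len(y_true)), idx], 1e-15, 1 - 1e-15)
    return float(-np.mean(np.log(p)))


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperparameterGrid,
    seed: int,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[float, float, pd.DataFrame]:
    """Repeated stratified k-fold tuning over the (alpha, lambda) grid.

    Returns the winning pair (argmin logLoss or argmax accuracy/kappa, ties
    broken by grid order) and the full CV table. Deterministic given seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < grid.cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {grid.cv_folds} folds; "
            "reduce cv_folds"
        )
    cv = RepeatedStratifiedKFold(
        n_splits=grid.cv_folds, n_repeats=grid.cv_repeats, random_state=seed
    )
    splits = list(cv.split(X, y))
    rows = []
    for alpha in grid.alphas:
        for lam in grid.lambdas:
            est = ElasticNetEthnicityClassifier(
                alpha=alpha, lam=lam, tol=tol, max_iter=max_iter, threshold=0.0
            )
            scores = []
            for train_idx, test_idx in splits:
                e = clone(est).fit(X[train_idx], y[train_idx])
                proba = e.predict_proba(X[test_idx])
                pred = e.classes_[proba.argmax(axis=1)]
                scores.append(
                    _metric_value(grid.selection_metric, y[test_idx], pred, proba, e.classes_)
                )
            rows.append({"alpha": alpha, "lambda": lam, grid.selection_metric: np.mean(scores)})
    table = pd.DataFrame(rows)
    if grid.selection_metric == "logLoss":
        best = table[grid.selection_metric].idxmin()
    else:
        best = table[grid.selection_metric].idxmax()
    return float(table.loc[best, "alpha"]), float(table.loc[best, "lambda"]), table


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineConfig:
    """End-to-end training configuration: cascade, grid, threshold, solver tol."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    grid: HyperparameterGrid = field(default_factory=HyperparameterGrid)
    threshold: float = DEFAULT_THRESHOLD
    tune_tol: float = 1e-4
    tune_max_iter: int = 200
    fit_tol: float = 1e-6
    fit_max_iter: int = 1000


def desk_scale_config() -> PipelineConfig:
    """A reduced tuning grid sized for the bundled synthetic cohorts."""
    return PipelineConfig(
        grid=HyperparameterGrid(
            alphas=(0.1, 0.5),
            lambdas=(0.003, 0.03, 0.25),
            cv_folds=3,
            cv_repeats=1,
        )
    )


def fit_pipeline(
    bm: BetaMatrix,
    ann: SiteAnnotation,
    sheet: SampleSheet,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> FittedClassifier:
    """Preprocess, tune, and fit the final model on all labelled samples."""
    config = config or PipelineConfig()
    processed, reports = run_preprocess(bm, ann, sheet, config.preprocess)
    eth = sheet.ethnicity().reindex(processed.sample_ids)
    labelled = eth.dropna().index
    if len(labelled) == 0:
        raise ValueError("no labels to train on: all reported ethnicities are missing")
    X = processed.beta[labelled].to_numpy().T
    y = eth.loc[labelled].to_numpy()
    best_alpha, best_lam, _ = tune_hyperparameters(
        X, y, config.grid, seed=seed, tol=config.tune_tol, max_iter=config.tune_max_iter
    )
    model = fit_elastic_net_multinomial(
        X, y, best_alpha, best_lam,
        site_ids=processed.site_ids.tolist(), tol=config.fit_tol,
        max_iter=config.fit_max_iter,
    )
    model.preprocessing_record = [r.to_record() for r in reports] + [
        {"step": "training", "n_sites": int(processed.n_sites),
         "n_samples": int(len(labelled)), "alpha": best_alpha, "lambda": best_lam,
         "seed": seed}
    ]
    return model
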