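"""Metrics, leave-one-dataset-out cross-validation, and classifier comparison.

Headline metrics count Ambiguous calls against accuracy (a sample the
classifier declined to place is not a correct classification); a variant
excluding ambiguous calls is reported alongside. LODOCV holds out an entire
cohort per fold: site filters, hyperparameter tuning, and the final fit all
see only the training cohorts, so the aggregate metrics estimate
cross-study generalization rather than within-study fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chi2
from sklearn.metrics import accuracy_score, cohen_kappa_score, confusion_matrix

from .classifier import (
    DEFAULT_THRESHOLD,
    PipelineConfig,
    call_ethnicity,
    fit_elastic_net_multinomial,
    predict_probabilities,
    tune_hyperparameters,
)
from .io import AMBIGUOUS, CLASSES, BetaMatrix, SampleSheet, SiteAnnotation, predictions_to_frame
from .preprocess import bmiq_normalize, run_preprocess

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Aggregate classification metrics for one evaluation set."""

    accuracy: float
    accuracy_excluding_ambiguous: float
    kappa: float
    ppv_per_class: dict[str, float]
    macro_ppv: float
    log_loss: float | None
    per_class_accuracy: dict[str, float]
    confusion: pd.DataFrame
    n_samples: int
    n_ambiguous: int
    per_dataset: dict[str, "EvaluationReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "accuracy_excluding_ambiguous": self.accuracy_excluding_ambiguous,
            "kappa": self.kappa,
            "ppv_per_class": self.ppv_per_class,
            "macro_ppv": self.macro_ppv,
            "log_loss": self.log_loss,
            "per_class_accuracy": self.per_class_accuracy,
            "n_samples": self.n_samples,
            "n_ambiguous": self.n_ambiguous,
        }
        if self.per_dataset:
            d["per_dataset"] = {k: v.to_dict() for k, v in self.per_dataset.items()}
        return d


def compute_metrics(
    truth,
    calls,
    probs: pd.DataFrame | None = None,
    datasets=None,
) -> EvaluationReport:
    """Accuracy / kappa / PPV / logLoss for aligned truth and call vectors.

    Ambiguous calls count as incorrect in ``accuracy`` and as their own call
    category in the confusion matrix; ``accuracy_excluding_ambiguous``
    restricts to confidently called samples. ``probs`` (samples x classes,
    aligned) is needed only for logLoss.
    """
    truth = np.asarray(truth, dtype=object)
    calls = np.asarray(calls, dtype=object)
    if len(truth) != len(calls):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(calls)} calls")
    known = set(CLASSES) | {AMBIGUOUS}
    unknown = (set(truth) | set(calls)) - known
    if unknown:
        raise ValueError(f"unknown labels: {sorted(map(str, unknown))}")

    labels = list(CLASSES) + [AMBIGUOUS]
    cm = confusion_matrix(truth, calls, labels=labels)
    confusion = pd.DataFrame(cm, index=labels, columns=labels)

    acc = accuracy_score(truth, calls)
    kappa = cohen_kappa_score(truth, calls, labels=labels)
    confident = calls != AMBIGUOUS
    acc_excl = accuracy_score(truth[confident], calls[confident]) if confident.any() else np.nan

    ppv = {}
    per_class_acc = {}
    for c in CLASSES:
        called_c = calls == c
        ppv[c] = float((truth[called_c] == c).mean()) if called_c.any() else np.nan
        truth_c = truth == c
        per_class_acc[c] = float((calls[truth_c] == c).mean()) if truth_c.any() else np.nan
    macro_ppv = float(np.nanmean(list(ppv.values())))

    ll = None
    if probs is not None:
        if len(probs) != len(truth):
            raise ValueError("probs not aligned with truth")
        arr = probs[list(CLASSES)].to_numpy()
        idx = np.array([list(CLASSES).index(t) if t in CLASSES else -1 for t in truth])
        ok = idx >= 0
        p = np.clip(arr[np.flatnonzero(ok), idx[ok]], 1e-15, 1 - 1e-15)
        ll = float(-np.mean(np.log(p)))

    report = EvaluationReport(
        accuracy=float(acc),
        accuracy_excluding_ambiguous=float(acc_excl),
        kappa=float(kappa),
        ppv_per_class=ppv,
        macro_ppv=macro_ppv,
        log_loss=ll,
        per_class_accuracy=per_class_acc,
        confusion=confusion,
        n_samples=len(truth),
        n_ambiguous=int((calls == AMBIGUOUS).sum()),
    )
    if datasets is not None:
        datasets = np.asarray(datasets)
        for d in pd.unique(datasets):
            sel = datasets == d
            report.per_dataset[str(d)] = compute_metrics(
                truth[sel], calls[sel], None if probs is None else probs.iloc[sel]
            )
    return report


# ---------------------------------------------------------------------------
# LODOCV


def _prepare_test_matrix(bm_test: BetaMatrix, ann, site_ids, config: PipelineConfig,
                         train_means: pd.Series) -> pd.DataFrame:
    """Held-out samples on the training site set: per-sample BMIQ, mean-fill."""
    present = [s for s in site_ids if s in bm_test.site_ids]
    sub = bm_test.subset_sites(present)
    if config.preprocess.bmiq:
        sub = bmiq_normalize(sub, ann, min_probes=config.preprocess.bmiq_min_probes)
    beta = sub.beta.reindex(site_ids)
    if beta.isna().any().any():
        fill = train_means.reindex(site_ids)
        beta = beta.apply(lambda col: col.fillna(fill))
    return beta


def lodocv(
    bm: BetaMatrix,
    ann: SiteAnnotation,
    sheet: SampleSheet,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, EvaluationReport], EvaluationReport, pd.DataFrame]:
    """Leave-one-dataset-out cross-validation of the full training pipeline.

    For each dataset the entire pipeline — QC site filters, hyperparameter
    tuning, and the final fit — is trained strictly without that dataset,
    then used to classify its samples. Returns per-dataset reports, the
    aggregate report pooling all held-out predictions, and the per-sample
    prediction table.
    """
    config = config or PipelineConfig()
    datasets = pd.unique(sheet.data["dataset_id"])
    if len(datasets) < 2:
        raise ValueError("LODOCV needs at least 2 dataset_ids")

    eth = sheet.ethnicity()
    all_preds = []
    per_dataset: dict[str, EvaluationReport] = {}

    for d in datasets:
        test_ids = sheet.data.loc[sheet.data["dataset_id"] == d, "sample_id"]
        test_ids = [s for s in test_ids if s in bm.sample_ids]
        train_sheet = sheet.subset(
            sheet.data.loc[sheet.data["dataset_id"] != d, "sample_id"]
        )
        train_ids = [s for s in train_sheet.sample_ids if s in bm.sample_ids]
        if not test_ids:
            raise ValueError(f"held-out dataset {d!r} has no samples in the matrix")

        bm_train = bm.subset_samples(train_ids)
        processed, reports = run_preprocess(bm_train, ann, train_sheet, config.preprocess)

        y = eth.reindex(processed.sample_ids).dropna()
        X = processed.beta[y.index].to_numpy().T
        best_alpha, best_lam, _ = tune_hyperparameters(
            X, y.to_numpy(), config.grid, seed=seed, tol=config.tune_tol,
            max_iter=config.tune_max_iter,
        )
        model = fit_elastic_net_multinomial(
            X, y.to_numpy(), best_alpha, best_lam,
            site_ids=processed.site_ids.tolist(), tol=config.fit_tol,
            max_iter=config.fit_max_iter,
        )
        model.preprocessing_record = [r.to_record() for r in reports]

        train_means = processed.beta.mean(axis=1)
        beta_test = _prepare_test_matrix(
            bm.subset_samples(test_ids), ann, processed.site_ids.tolist(), config, train_means
        )
        probs = predict_probabilities(model, beta_test)
        results = call_ethnicity(probs, threshold=config.threshold)
        frame = predictions_to_frame(results)
        frame["dataset_id"] = d
        frame["truth"] = eth.reindex(frame["sample_id"]).to_numpy()
        all_preds.append(frame)

        labelled = frame["truth"].notna()
        if labelled.any():
            per_dataset[str(d)] = compute_metrics(
                frame.loc[labelled, "truth"],
                frame.loc[labelled, "predicted"],
                frame.loc[labelled, ["prob_African", "prob_Asian", "prob_Caucasian"]]
                .rename(columns=lambda c: c.replace("prob_", "")),
            )

    pooled = pd.concat(all_preds, ignore_index=True)
    labelled = pooled["truth"].notna()
    aggregate = compute_metrics(
        pooled.loc[labelled, "truth"],
        pooled.loc[labelled, "predicted"],
        pooled.loc[labelled, ["prob_African", "prob_Asian", "prob_Caucasian"]]
        .rename(columns=lambda c: c.replace("prob_", "")),
        datasets=pooled.loc[labelled, "dataset_id"],
    )
    return per_dataset, aggregate, pooled


# ---------------------------------------------------------------------------
# threshold sweep


def threshold_sweep(
    probs: pd.DataFrame,
    truth,
    thresholds=None,
) -> pd.DataFrame:
    """Accuracy / kappa / ambiguous fraction across confidence cutoffs.

    The fraction of ambiguous calls is non-decreasing in the threshold by
    construction (a sample ambiguous at t is ambiguous at every t' > t).
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.50, 0.951, 0.05), 2)
    truth = np.asarray(truth, dtype=object)
    rows = []
    for t in thresholds:
        calls = np.asarray([r.predicted for r in call_ethnicity(probs, threshold=float(t))],
                           dtype=object)
        rep = compute_metrics(truth, calls)
        rows.append(
            {
                "threshold": float(t),
                "accuracy": rep.accuracy,
                "kappa": rep.kappa,
                "fraction_ambiguous": rep.n_ambiguous / rep.n_samples,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# McNemar


def mcnemar_test(truth, calls_a, calls_b) -> tuple[int, int, float, float]:
    """Paired comparison of two classifiers by McNemar's test.

    ``b`` counts samples A got right and B wrong, ``c`` the reverse. The
    statistic is the continuity-corrected (|b-c|-1)^2/(b+c) against
    chi-square(1); when b+c < 25 the p-value comes from the exact binomial
    instead.
    """
    truth = np.asarray(truth, dtype=object)
    calls_a = np.asarray(calls_a, dtype=object)
    calls_b = np.asarray(calls_b, dtype=object)
    if not (len(truth) == len(calls_a) == len(calls_b)):
        raise ValueError("truth, calls_a, calls_b must be aligned")
    a_ok = calls_a == truth
    b_ok = calls_b == truth
    b = int((a_ok & ~b_ok).sum())
    c = int((~a_ok & b_ok).sum())
    if b + c == 0:
        logger.info("McNemar: no discordant pairs; p = 1 by convention")
        return b, c, 0.0, 1.0
    stat = (abs(b - c) - 1) ** 2 / (b + c)
    if b + c < 25:
        p = binomtest(b, b + c, 0.5).pvalue
    else:
        p = float(chi2.sf(stat, df=1))
    return b, c, float(stat), float(p)
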