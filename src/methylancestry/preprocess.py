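"""QC / filtering cascade producing the analysis-ready beta matrix.

The cascade runs, in order: restriction to the cross-platform probe set,
removal of poor-quality sites (detection p / bead count), KNN imputation of
the surviving failed measurements, removal of cross-hybridizing and
tissue-non-variable sites, sample-level QC (inter-array correlation, then
sex concordance), and finally BMIQ normalization of type II probes. Each
filtering step emits a :class:`FilterReport` with the exact ids removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.special import betainc, betaln
from sklearn.impute import KNNImputer

from .io import BetaMatrix, SampleSheet, SiteAnnotation

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """One executed cascade step: what was removed and with which parameters."""

    step: str
    sites_removed: list[str] = field(default_factory=list)
    samples_removed: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    @property
    def n_sites_removed(self) -> int:
        return len(self.sites_removed)

    @property
    def n_samples_removed(self) -> int:
        return len(self.samples_removed)

    def to_record(self) -> dict:
        return {
            "step": self.step,
            "n_sites_removed": self.n_sites_removed,
            "n_samples_removed": self.n_samples_removed,
            "parameters": dict(self.parameters),
        }


@dataclass
class PreprocessConfig:
    """Cascade parameters, defaulting to the standard thresholds."""

    platform_overlap: bool = True
    quality_filter: bool = True
    max_fail_fraction: float = 0.01
    detect_thresh: float = 0.01
    min_beads: int = 3
    impute: bool = True
    knn_k: int = 10
    flag_filter: bool = True
    drop_flags: tuple[str, ...] = ("cross_hybridizing", "nonvariable")
    sample_qc: bool = True
    min_interarray_r: float = 0.95
    sex_check: bool = True
    bmiq: bool = True
    bmiq_min_probes: int = 500


# ---------------------------------------------------------------------------
# site filters


def restrict_to_platform_overlap(bm: BetaMatrix, ann: SiteAnnotation) -> tuple[BetaMatrix, FilterReport]:
    """Keep only sites assayed on both array generations (on_epic flag)."""
    unannotated = bm.site_ids.difference(ann.site_ids)
    if len(unannotated):
        raise ValueError(f"unannotated sites: {list(unannotated[:10])}")
    flags = ann.for_sites(bm.site_ids)["on_epic"]
    keep = bm.site_ids[flags.to_numpy()]
    removed = bm.site_ids.difference(keep).tolist()
    report = FilterReport("platform_overlap", sites_removed=sorted(removed))
    return bm.subset_sites(keep), report


def filter_poor_quality_sites(
    bm: BetaMatrix,
    max_fail_fraction: float = 0.01,
    detect_thresh: float = 0.01,
    min_beads: int = 3,
) -> tuple[BetaMatrix, FilterReport]:
    """Drop sites failing in strictly more than ``max_fail_fraction`` of samples.

    A measurement fails iff detection p > ``detect_thresh`` OR bead count
    < ``min_beads``. Sites kept despite isolated failures have those
    measurements masked to missing for downstream imputation.
    """
    params = {
        "max_fail_fraction": max_fail_fraction,
        "detect_thresh": detect_thresh,
        "min_beads": min_beads,
    }
    if bm.detection_p is None and bm.bead_count is None:
        logger.warning("no detection-p or bead-count layer: quality filter is a no-op")
        return bm, FilterReport("quality_filter", parameters=params)

    fails = np.zeros(bm.beta.shape, dtype=bool)
    if bm.detection_p is not None:
        fails |= bm.detection_p.to_numpy() > detect_thresh
    if bm.bead_count is not None:
        fails |= bm.bead_count.to_numpy() < min_beads

    frac = fails.mean(axis=1)
    drop = frac > max_fail_fraction  # strictly greater
    removed = bm.site_ids[drop].tolist()
    out = bm.subset_sites(bm.site_ids[~drop])
    # mask surviving failures to missing
    surviving_fails = fails[~drop]
    if surviving_fails.any():
        masked = out.beta.to_numpy(copy=True)
        masked[surviving_fails] = np.nan
        out = BetaMatrix(
            beta=pd.DataFrame(masked, index=out.site_ids, columns=out.sample_ids),
            detection_p=out.detection_p,
            bead_count=out.bead_count,
        )
    return out, FilterReport("quality_filter", sites_removed=removed, parameters=params)


def impute_knn(bm: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Replace missing betas with the mean of the k nearest sites' values.

    Nearness between sites is nan-aware Euclidean distance over the samples
    observed in both (with the standard sqrt(total/shared) rescaling).
    Observed values are never altered.
    """
    vals = bm.beta.to_numpy()
    if not np.isnan(vals).any():
        return bm
    all_missing = np.isnan(vals).all(axis=1)
    if all_missing.any():
        bad = bm.site_ids[all_missing].tolist()
        raise ValueError(f"sites with no observed values cannot be imputed: {bad[:10]}")
    n_sites = vals.shape[0]
    if k >= n_sites:
        logger.warning("knn k=%d >= %d sites; using all other sites", k, n_sites)
        k = max(1, n_sites - 1)
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    # sites as rows: neighbours are other sites, imputed cell = mean of their
    # values at the same sample
    imputed = imputer.fit_transform(vals)
    out = vals.copy()
    mask = np.isnan(vals)
    out[mask] = imputed[mask]
    return BetaMatrix(
        beta=pd.DataFrame(out, index=bm.site_ids, columns=bm.sample_ids),
        detection_p=bm.detection_p,
        bead_count=bm.bead_count,
    )


def remove_flagged_sites(
    bm: BetaMatrix,
    ann: SiteAnnotation,
    drop: tuple[str, ...] = ("cross_hybridizing", "nonvariable"),
) -> tuple[BetaMatrix, FilterReport]:
    """Remove sites carrying any of the listed QC flags.

    SNP-class probes are exempt from the non-variable flag: their variability
    is genotype, which is exactly the signal of interest.
    """
    sub = ann.for_sites(bm.site_ids)
    is_snp = (sub["probe_class"] == "SNP").to_numpy()
    remove = np.zeros(bm.n_sites, dtype=bool)
    for flag in drop:
        flagged = sub[flag].to_numpy()
        if flag == "nonvariable":
            flagged = flagged & ~is_snp
        remove |= flagged
    removed = bm.site_ids[remove].tolist()
    report = FilterReport("flagged_sites", sites_removed=removed, parameters={"drop": list(drop)})
    return bm.subset_sites(bm.site_ids[~remove]), report


# ---------------------------------------------------------------------------
# sample QC


def infer_sex(bm: BetaMatrix, ann: SiteAnnotation, sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Infer sample sex by 2-cluster hierarchical clustering on sex-chromosome betas.

    Average-linkage, Euclidean; the cluster with higher mean chrY methylation
    is labelled male. Returns a frame with inferred sex and, when a sheet
    with reported sex is given, a concordance flag.
    """
    sub = ann.for_sites(bm.site_ids)
    sex_sites = bm.site_ids[(sub["chromosome"].isin(["X", "Y"])).to_numpy()]
    if len(sex_sites) < 2:
        raise ValueError("need at least 2 sex-chromosome sites to infer sex")
    if bm.n_samples < 2:
        raise ValueError("need at least 2 samples to infer sex")
    data = bm.beta.loc[sex_sites].to_numpy().T  # samples x sex sites
    labels = fcluster(linkage(pdist(data), method="average"), t=2, criterion="maxclust")

    y_sites = bm.site_ids[(sub["chromosome"] == "Y").to_numpy()]
    if len(y_sites) == 0:
        y_mat = bm.beta.loc[sex_sites]  # fall back to all sex-chromosome sites
    else:
        y_mat = bm.beta.loc[y_sites]
    chry_mean = y_mat.mean(axis=0).to_numpy()

    if len(np.unique(labels)) < 2:
        logger.warning("sex clustering degenerate: all samples in one cluster")
        inferred = np.array(["U"] * bm.n_samples, dtype=object)
    else:
        means = {c: chry_mean[labels == c].mean() for c in np.unique(labels)}
        male_cluster = max(means, key=means.get)
        inferred = np.where(labels == male_cluster, "M", "F").astype(object)

    out = pd.DataFrame({"sample_id": bm.sample_ids, "inferred_sex": inferred})
    if sheet is not None and "reported_sex" in sheet.data.columns:
        rep = sheet.data.set_index("sample_id")["reported_sex"].reindex(bm.sample_ids)
        out["reported_sex"] = rep.to_numpy()
        out["concordant"] = [
            True if (pd.isna(r) or i == "U") else (i == r)
            for i, r in zip(out["inferred_sex"], out["reported_sex"])
        ]
    return out


def interarray_correlation_filter(
    bm: BetaMatrix, min_r: float = 0.95, max_remove_fraction: float = 0.2
) -> tuple[BetaMatrix, pd.Series, FilterReport]:
    """Drop samples whose mean Pearson correlation with the others falls below min_r.

    Removal is iterative: the worst sample below the cutoff is dropped and
    the means recomputed, so one grossly aberrant array cannot drag its
    neighbours' means below the threshold. At most ``max_remove_fraction``
    of the samples are removed; hitting the cap suggests a cohort-level
    problem rather than individual bad arrays, and is logged loudly.
    """
    if bm.n_samples < 3:
        raise ValueError("need at least 3 samples for a stable mean inter-array correlation")
    corr = bm.beta.corr(method="pearson")  # pairwise-complete
    np.fill_diagonal(corr.values, np.nan)
    initial_mean_r = corr.mean(axis=0)
    if min_r <= 0:  # threshold 0 disables the filter
        return bm, initial_mean_r, FilterReport(
            "interarray_correlation", parameters={"min_r": min_r}
        )

    kept = list(bm.sample_ids)
    removed: list[str] = []
    cap = max(1, int(np.floor(max_remove_fraction * bm.n_samples)))
    while len(kept) >= 3:
        mean_r = corr.loc[kept, kept].mean(axis=0)
        worst = mean_r.idxmin()
        if mean_r[worst] >= min_r:
            break
        if len(removed) >= cap:
            logger.warning(
                "inter-array filter stopped at the %.0f%% removal cap with samples "
                "still below r=%.2f — the whole batch correlates poorly",
                100 * max_remove_fraction, min_r,
            )
            break
        removed.append(worst)
        kept.remove(worst)
    report = FilterReport(
        "interarray_correlation",
        samples_removed=removed,
        parameters={"min_r": min_r},
    )
    return bm.subset_samples(kept), initial_mean_r, report


def sex_concordance_filter(
    bm: BetaMatrix, ann: SiteAnnotation, sheet: SampleSheet
) -> tuple[BetaMatrix, pd.DataFrame, FilterReport]:
    """Drop samples whose clustered sex disagrees with the reported sex."""
    table = infer_sex(bm, ann, sheet)
    if "concordant" not in table.columns:
        return bm, table, FilterReport("sex_concordance")
    discordant = table.loc[~table["concordant"], "sample_id"].tolist()
    keep = [s for s in bm.sample_ids if s not in set(discordant)]
    report = FilterReport("sex_concordance", samples_removed=discordant)
    return bm.subset_samples(keep), table, report


# ---------------------------------------------------------------------------
# BMIQ


def _fit_beta_mixture(
    x: np.ndarray, n_states: int = 3, max_iter: int = 100, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM fit of an ``n_states``-component beta mixture.

    Initialized by quantile thirds; M-step by weighted moment matching.
    Returns (weights, a, b) with components sorted by mean.
    """
    eps = 1e-6
    x = np.clip(np.asarray(x, dtype=float), eps, 1 - eps)
    n = len(x)
    # init: split at empirical quantiles
    edges = np.quantile(x, np.linspace(0, 1, n_states + 1))
    a = np.empty(n_states)
    b = np.empty(n_states)
    w = np.full(n_states, 1.0 / n_states)
    for k in range(n_states):
        lo, hi = edges[k], edges[k + 1]
        sel = x[(x >= lo) & (x <= hi)]
        if len(sel) < 2:
            sel = x
        m, v = sel.mean(), max(sel.var(), 1e-6)
        v = min(v, m * (1 - m) * 0.99)
        common = m * (1 - m) / v - 1
        a[k], b[k] = max(m * common, 0.05), max((1 - m) * common, 0.05)

    lx = np.log(x)
    l1x = np.log1p(-x)
    prev_ll = -np.inf
    for _ in range(max_iter):
        # beta log-pdf by hand: (a-1) log x + (b-1) log(1-x) - B(a, b)
        logpdf = (
            (a[:, None] - 1) * lx
            + (b[:, None] - 1) * l1x
            - betaln(a, b)[:, None]
            + np.log(w)[:, None]
        )
        mx = logpdf.max(axis=0)
        lse = mx + np.log(np.exp(logpdf - mx).sum(axis=0))
        resp = np.exp(logpdf - lse)
        ll = lse.sum()
        if abs(ll - prev_ll) < tol * max(1.0, abs(prev_ll)):
            break
        prev_ll = ll
        nk = resp.sum(axis=1)
        w = nk / n
        m = resp @ x / nk
        v = resp @ (x**2) / nk - m**2
        v = np.clip(v, 1e-8, m * (1 - m) * 0.999)
        common = m * (1 - m) / v - 1
        a = np.maximum(m * common, 0.05)
        b = np.maximum((1 - m) * common, 0.05)

    order = np.argsort(a / (a + b))
    return w[order], a[order], b[order]


def _mixture_cdf(grid: np.ndarray, w: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return sum(w[k] * betainc(a[k], b[k], grid) for k in range(len(w)))


def bmiq_normalize(
    bm: BetaMatrix,
    ann: SiteAnnotation,
    min_probes: int = 500,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> BetaMatrix:
    """Beta-mixture quantile normalization of type II probes onto type I.

    Per sample, 3-state (unmethylated / hemimethylated / methylated) beta
    mixtures are fitted to the type I and type II CpG distributions; type II
    values are mapped through the fitted type II mixture CDF and back through
    the inverse of the type I mixture CDF. The mapping is monotone, so
    within-sample rank order among type II probes is preserved. SNP-class
    probes and type I values pass through unchanged.
    """
    sub = ann.for_sites(bm.site_ids)
    is_cpg = (sub["probe_class"] == "CpG").to_numpy()
    type1 = is_cpg & (sub["design_type"] == "I").to_numpy()
    type2 = is_cpg & (sub["design_type"] == "II").to_numpy()
    if type1.sum() < min_probes or type2.sum() < min_probes:
        logger.warning(
            "BMIQ skipped: %d type I / %d type II probes (< %d)",
            type1.sum(), type2.sum(), min_probes,
        )
        return bm

    vals = bm.beta.to_numpy(copy=True)
    grid = np.linspace(1e-6, 1 - 1e-6, 2001)
    for j in range(vals.shape[1]):
        x1 = vals[type1, j]
        x2 = vals[type2, j]
        ok1, ok2 = ~np.isnan(x1), ~np.isnan(x2)
        w1, a1, b1 = _fit_beta_mixture(x1[ok1], max_iter=max_iter, tol=tol)
        w2, a2, b2 = _fit_beta_mixture(x2[ok2], max_iter=max_iter, tol=tol)
        cdf2 = _mixture_cdf(np.clip(x2[ok2], 1e-6, 1 - 1e-6), w2, a2, b2)
        cdf1_grid = _mixture_cdf(grid, w1, a1, b1)
        mapped = np.interp(cdf2, cdf1_grid, grid)
        new2 = x2.copy()
        new2[ok2] = np.clip(mapped, 0.0, 1.0)
        vals[type2, j] = new2
    return BetaMatrix(
        beta=pd.DataFrame(vals, index=bm.site_ids, columns=bm.sample_ids),
        detection_p=bm.detection_p,
        bead_count=bm.bead_count,
    )


# ---------------------------------------------------------------------------
# full cascade


def run_preprocess(
    bm: BetaMatrix,
    ann: SiteAnnotation,
    sheet: SampleSheet | None = None,
    config: PreprocessConfig | None = None,
) -> tuple[BetaMatrix, list[FilterReport]]:
    """Run the full QC cascade in order, returning the matrix and step reports."""
    config = config or PreprocessConfig()
    reports: list[FilterReport] = []

    if config.platform_overlap:
        bm, rep = restrict_to_platform_overlap(bm, ann)
        reports.append(rep)
    if config.quality_filter:
        bm, rep = filter_poor_quality_sites(
            bm,
            max_fail_fraction=config.max_fail_fraction,
            detect_thresh=config.detect_thresh,
            min_beads=config.min_beads,
        )
        reports.append(rep)
    if config.impute:
        bm = impute_knn(bm, k=config.knn_k)
    if config.flag_filter:
        bm, rep = remove_flagged_sites(bm, ann, drop=config.drop_flags)
        reports.append(rep)
    if config.sample_qc:
        bm, _, rep = interarray_correlation_filter(bm, min_r=config.min_interarray_r)
        reports.append(rep)
        if config.sex_check and sheet is not None:
            bm, _, rep = sex_concordance_filter(bm, ann, sheet)
            reports.append(rep)
    if config.bmiq:
        bm = bmiq_normalize(bm, ann, min_probes=config.bmiq_min_probes)
    return bm, reports
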