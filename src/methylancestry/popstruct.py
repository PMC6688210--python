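"""PCA variance-explained framework for comparing population-structure methods.

Different inference methods (an ethnicity classifier's selected sites, SNP
probes, variant-adjacent CpG filters, user-supplied reference lists) reduce
to site subsets; PCA on standardized betas over each subset yields scores
whose association with ethnicity, genetic-ancestry coordinates, and nuisance
covariates is quantified by simple-regression R-squared per component. A
method is good for population-structure adjustment when its top components
load on ancestry rather than batch or biology.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import BetaMatrix, SampleSheet, SiteAnnotation

logger = logging.getLogger(__name__)


class SiteSetRegistry(dict):
    """Named site subsets for method comparison; validated against an annotation."""

    def __init__(self, ann: SiteAnnotation | None = None, **sets: Iterable[str]):
        super().__init__()
        self._ann = ann
        for name, sites in sets.items():
            self.register(name, sites)

    def register(self, name: str, sites: Iterable[str]) -> None:
        if name in self:
            raise ValueError(f"site set {name!r} already registered")
        sites = list(dict.fromkeys(sites))
        if self._ann is not None:
            unknown = pd.Index(sites).difference(self._ann.site_ids)
            if len(unknown):
                raise KeyError(f"sites not in annotation: {list(unknown[:5])}")
        self[name] = sites


def standardize_betas(bm: BetaMatrix, sites: Iterable[str]) -> pd.DataFrame:
    """Z-score each site across samples; zero-variance sites are dropped."""
    sites = pd.Index(sites)
    if len(sites) == 0:
        raise ValueError("empty site set")
    sub = bm.beta.loc[sites.intersection(bm.site_ids)]
    vals = sub.to_numpy()
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        logger.warning("dropping %d constant site(s) before standardization", constant.sum())
    z = (vals[~constant] - mean[~constant]) / sd[~constant]
    return pd.DataFrame(z, index=sub.index[~constant], columns=sub.columns)


def pca_scores(
    std_matrix: pd.DataFrame, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and variance fractions from PCA on a sites x samples z-matrix.

    Components are ordered by decreasing explained variance with a
    deterministic sign: the loading of largest magnitude is made positive.
    """
    X = std_matrix.to_numpy().T  # samples x sites
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        logger.warning("n_components=%d clamped to rank %d", n_components, max_rank)
        n_components = max(1, max_rank)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # fixed sign convention for reproducibility
    for k in range(scores.shape[1]):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=std_matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def variance_explained(pc_scores: pd.DataFrame, covariate) -> pd.Series:
    """R-squared from OLS of each PC on the covariate(s).

    ``covariate`` may be numeric, categorical (expanded to indicators), or a
    DataFrame of several columns fitted jointly (e.g. two ancestry
    coordinates). A constant covariate yields R-squared 0 with a note.
    """
    if isinstance(covariate, pd.DataFrame):
        design = covariate.to_numpy(dtype=float)
    else:
        cov = pd.Series(np.asarray(covariate), index=pc_scores.index)
        if cov.dtype == object or isinstance(cov.dtype, pd.CategoricalDtype):
            design = pd.get_dummies(cov, drop_first=True).to_numpy(dtype=float)
        else:
            design = cov.to_numpy(dtype=float)[:, None]
    if design.shape[1] == 0 or np.all(np.ptp(design, axis=0) == 0):
        logger.warning("constant covariate: R^2 undefined, reported as 0")
        return pd.Series(0.0, index=pc_scores.columns)
    X = np.column_stack([np.ones(len(design)), design])
    out = {}
    for col in pc_scores.columns:
        y = pc_scores[col].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sst = np.sum((y - y.mean()) ** 2)
        out[col] = 0.0 if sst == 0 else float(1 - np.sum(resid**2) / sst)
    return pd.Series(out)


def barfield_distance_sets(
    ann: SiteAnnotation, distances: Iterable[int] = (0, 1, 2, 5, 10, 50)
) -> dict[str, list[str]]:
    """Nested CpG site sets within each distance of a known genetic variant."""
    df = ann.data
    if df["dist_to_variant"].isna().all():
        raise ValueError("annotation has no dist_to_variant information")
    cpg = df[df["probe_class"] == "CpG"]
    out = {}
    for d in sorted(distances):
        mask = cpg["dist_to_variant"].notna() & (cpg["dist_to_variant"] <= d)
        out[f"snp_adjacent_d{d}"] = cpg.loc[mask, "site_id"].tolist()
    return out


def compare_methods(
    bm: BetaMatrix,
    ann: SiteAnnotation,
    sheet: SampleSheet,
    registry: Mapping[str, Iterable[str]],
    ancestry: pd.DataFrame | None = None,
    lodocv_sites: Mapping[str, Iterable[str]] | None = None,
    n_components: int = 10,
    scope: str = "within_cohort",
) -> pd.DataFrame:
    """Per-cohort PCA + variance-explained table for every registered site set.

    Standardization and PCA run within each cohort by default; with
    ``scope="global"`` they run once over all samples pooled and the
    regressions still run per cohort on the global scores (cohort labelled
    ``all`` when a single pooled analysis is wanted is simply the union).
    ``lodocv_sites`` maps
    cohort -> classifier-selected sites from a model trained with that cohort
    held out; the resulting set is named ``classifier_selected`` and avoids
    evaluating a method on the samples that chose its sites. ``ancestry``
    (samples x >=2 coordinate columns) adds a joint coordinate-1+2 model and
    single-coordinate models.
    """
    if scope not in ("within_cohort", "global"):
        raise ValueError("scope must be 'within_cohort' or 'global'")
    global_cache: dict[str, tuple[pd.DataFrame, np.ndarray]] = {}
    if scope == "global":
        for name, sites in registry.items():
            usable = pd.Index(sites).intersection(bm.site_ids)
            if len(usable) == 0:
                continue
            z = standardize_betas(bm, usable)
            if z.shape[0]:
                global_cache[name] = pca_scores(z, n_components=n_components)
        if lodocv_sites is not None:
            logger.warning(
                "global scope ignores lodocv_sites (per-cohort site sets need "
                "within-cohort PCA)"
            )
            lodocv_sites = None

    rows = []
    eth = sheet.ethnicity()
    for cohort in pd.unique(sheet.data["dataset_id"]):
        ids = [
            s
            for s in sheet.data.loc[sheet.data["dataset_id"] == cohort, "sample_id"]
            if s in bm.sample_ids
        ]
        if len(ids) < 3:
            logger.warning("cohort %s has <3 samples; skipped", cohort)
            continue
        sub = bm.subset_samples(ids)
        sets = dict(registry)
        if lodocv_sites is not None and cohort in lodocv_sites:
            sets["classifier_selected"] = list(lodocv_sites[cohort])
        for name, sites in sets.items():
            if scope == "global":
                if name not in global_cache:
                    logger.warning("site set %s empty; skipped", name)
                    continue
                all_scores, var_frac = global_cache[name]
                scores = all_scores.loc[ids]
                usable = pd.Index(sites).intersection(bm.site_ids)
            else:
                usable = pd.Index(sites).intersection(sub.site_ids)
                if len(usable) == 0:
                    logger.warning("site set %s empty in cohort %s; skipped", name, cohort)
                    continue
                z = standardize_betas(sub, usable)
                if z.shape[0] == 0:
                    continue
                scores, var_frac = pca_scores(z, n_components=n_components)
            covs: dict[str, object] = {}
            e = eth.reindex(ids)
            if e.notna().sum() >= 3 and e.dropna().nunique() >= 2:
                covs["ethnicity"] = e.fillna("missing")
            for c in sheet.covariate_names:
                col = sheet.data.set_index("sample_id")[c].reindex(ids)
                if col.notna().sum() >= 3:
                    covs[c] = col
            if ancestry is not None:
                anc = ancestry.reindex(ids)
                if anc.notna().all(axis=1).sum() >= 3:
                    coords = anc.columns[:2]
                    covs["ancestry_coord1+2"] = anc[coords]
                    for coord in anc.columns:
                        covs[f"ancestry_{coord}"] = anc[coord]
            for cov_name, cov in covs.items():
                r2 = variance_explained(scores, cov)
                for pc, value in r2.items():
                    rows.append(
                        {
                            "cohort": cohort,
                            "site_set": name,
                            "n_sites": len(usable),
                            "pc": pc,
                            "variance_fraction": float(
                                var_frac[int(pc[2:]) - 1]
                            ),
                            "covariate": cov_name,
                            "r2": value,
                        }
                    )
    return pd.DataFrame(rows)
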