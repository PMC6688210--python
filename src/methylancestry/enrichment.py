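"""Fisher's-exact enrichment of classifier-selected sites over annotation features.

The background is the full site set available to the model at training; the
foreground is the sites the penalty kept (nonzero coefficient in at least
one class). Enrichment for SNP probes, SNP-in-probe CpGs and mQTLs is the
signature of a classifier that keys on genetic rather than purely epigenetic
variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import hypergeom

from .io import CHROMOSOMES, ISLAND_RELATIONS, FittedClassifier, SiteAnnotation

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One 2x2 enrichment test: selected/background x has/lacks feature."""

    feature: str
    a: int  # selected, has feature
    b: int  # selected, lacks feature
    c: int  # background (not selected), has feature
    d: int  # background (not selected), lacks feature
    odds_ratio: float
    p_two_sided: float
    p_greater: float

    @property
    def significant(self) -> bool:
        return self.p_two_sided < 0.05


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Exact hypergeometric test on [[a, b], [c, d]].

    Returns (odds ratio, two-sided p, upper-tail p of X >= a). Two-sided
    follows the sum-of-no-more-probable-tables convention. A zero margin
    gives p = 1 with the odds ratio undefined (NaN).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a + b, c + d, a + c, b + d) == 0:
        logger.info("fisher_exact_2x2: zero margin, p = 1 and OR undefined")
        return float("nan"), 1.0, 1.0
    table = [[a, b], [c, d]]
    odds, p_two = _scipy_fisher(table, alternative="two-sided")
    # upper tail in log-space-capable form: X ~ Hypergeom(M=a+b+c+d, n=a+c, N=a+b)
    p_greater = float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
    odds = float(odds) if np.isfinite(odds) else float("inf")
    return odds, float(p_two), min(p_greater, 1.0)


def snp_probe_enrichment_p(
    n_selected_snp: int = 15,
    n_selected: int = 1860,
    n_snp: int = 59,
    n_background: int = 319_292,
) -> float:
    """Upper-tail hypergeometric p for SNP probes among selected sites.

    Defaults reproduce the canonical check: 15 of 59 SNP probes among 1860
    selected sites from a 319,292-site background.
    """
    a = n_selected_snp
    b = n_selected - n_selected_snp
    c = n_snp - n_selected_snp
    d = n_background - n_selected - c
    return fisher_exact_2x2(a, b, c, d)[2]


DEFAULT_FEATURES = ("snp_probe", "snp_in_probe", "mqtl", "chromosome", "island_relation")


def enrichment_report(
    model: FittedClassifier,
    ann: SiteAnnotation,
    features=DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Per-feature enrichment of the model's selected sites vs its background.

    Chromosome and island-relation features are tested each-level-vs-rest.
    No multiple-testing correction is applied to the significance flag, but a
    Benjamini-Hochberg column is included for transparency.
    """
    background = pd.Index(model.model_sites)
    selected = set(model.selected_sites)
    if not selected:
        logger.warning("model has no selected sites; empty enrichment report")
        return pd.DataFrame(
            columns=["feature", "a", "b", "c", "d", "odds_ratio",
                     "p_two_sided", "p_greater", "significant", "p_bh"]
        )
    sub = ann.for_sites(background)
    sel_mask = sub.index.isin(selected)

    tests: list[tuple[str, np.ndarray]] = []
    for feat in features:
        if feat == "snp_probe":
            tests.append(("snp_probe", (sub["probe_class"] == "SNP").to_numpy()))
        elif feat in ("snp_in_probe", "mqtl", "cross_hybridizing", "nonvariable"):
            if feat not in sub.columns:
                logger.warning("feature %s absent from annotation; skipped", feat)
                continue
            tests.append((feat, sub[feat].to_numpy().astype(bool)))
        elif feat == "chromosome":
            for level in CHROMOSOMES:
                mask = (sub["chromosome"] == level).to_numpy()
                if mask.any():
                    tests.append((f"chr{level}", mask))
        elif feat == "island_relation":
            for level in ISLAND_RELATIONS:
                mask = (sub["island_relation"] == level).to_numpy()
                if mask.any():
                    tests.append((level, mask))
        else:
            logger.warning("unknown feature %s skipped", feat)

    rows = []
    for name, has in tests:
        a = int((sel_mask & has).sum())
        b = int((sel_mask & ~has).sum())
        c = int((~sel_mask & has).sum())
        d = int((~sel_mask & ~has).sum())
        odds, p_two, p_greater = fisher_exact_2x2(a, b, c, d)
        rows.append(
            {
                "feature": name,
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": odds,
                "p_two_sided": p_two,
                "p_greater": p_greater,
                "significant": p_two < 0.05,
            }
        )
    out = pd.DataFrame(rows)
    # Benjamini-Hochberg over the two-sided p's
    m = len(out)
    order = out["p_two_sided"].to_numpy().argsort()
    ranked = out["p_two_sided"].to_numpy()[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    bh = np.empty(m)
    bh[order] = np.clip(adj, 0, 1)
    out["p_bh"] = bh
    return out
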