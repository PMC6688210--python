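"""Domain types and readers/writers.

Matrices are stored sites-as-rows (array-manifest convention): the first
column holds probe identifiers, the header row holds sample identifiers.
Delimiters are auto-detected between comma and tab; missing values are
empty cells; everything is UTF-8.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1

#: Canonical ethnicity labels, in fixed (alphabetical) order. The order is
#: load-bearing: ties in classification are broken by it.
CLASSES = ("African", "Asian", "Caucasian")

AMBIGUOUS = "Ambiguous"

#: Versioned alias table mapping self-reported ethnicity strings onto the
#: three canonical labels. Unknown strings become missing with a warning.
ETHNICITY_ALIASES = {
    "african": "African",
    "black": "African",
    "black/african american": "African",
    "african american": "African",
    "asian": "Asian",
    "east asian": "Asian",
    "caucasian": "Caucasian",
    "white": "Caucasian",
    "caucasian/white": "Caucasian",
    "european": "Caucasian",
}

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


def _read_delimited(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a comma- or tab-delimited table, sniffing the delimiter."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    return pd.read_csv(path, sep=sep, index_col=index_col)


# ---------------------------------------------------------------------------
# BetaMatrix


@dataclass
class BetaMatrix:
    """Sites x samples methylation fractions with optional QC layers.

    ``beta`` holds methylation fractions in [0, 1] (NaN = missing);
    ``detection_p`` and ``bead_count``, when present, are aligned matrices
    of per-measurement detection p-values and bead counts.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    bead_count: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.beta = self.beta.astype(float)
        if self.beta.index.has_duplicates:
            dupes = self.beta.index[self.beta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate site ids: {dupes[:5]}")
        if self.beta.columns.has_duplicates:
            dupes = self.beta.columns[self.beta.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        vals = self.beta.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bad = np.nansum((vals < 0) | (vals > 1))
        if bad:
            raise ValueError(f"beta value out of range [0, 1] at {int(bad)} cells")
        for name in ("detection_p", "bead_count"):
            layer = getattr(self, name)
            if layer is None:
                continue
            if not layer.index.equals(self.beta.index) or not layer.columns.equals(
                self.beta.columns
            ):
                raise ValueError(
                    f"layer '{name}' is misaligned with the beta matrix "
                    "(site/sample ids or ordering differ)"
                )

    @property
    def site_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_sites(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_sites(self, sites: Iterable[str]) -> "BetaMatrix":
        sites = pd.Index(sites)
        return BetaMatrix(
            beta=self.beta.loc[sites],
            detection_p=None if self.detection_p is None else self.detection_p.loc[sites],
            bead_count=None if self.bead_count is None else self.bead_count.loc[sites],
        )

    def subset_samples(self, samples: Iterable[str]) -> "BetaMatrix":
        samples = pd.Index(samples)
        return BetaMatrix(
            beta=self.beta[samples],
            detection_p=None if self.detection_p is None else self.detection_p[samples],
            bead_count=None if self.bead_count is None else self.bead_count[samples],
        )

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            beta=self.beta.copy(),
            detection_p=None if self.detection_p is None else self.detection_p.copy(),
            bead_count=None if self.bead_count is None else self.bead_count.copy(),
        )


def read_beta_matrix(
    path: str | Path,
    detection_path: str | Path | None = None,
    beadcount_path: str | Path | None = None,
) -> BetaMatrix:
    """Read a beta matrix and optional aligned detection-p / bead-count layers."""
    beta = _read_delimited(path)
    detection_p = _read_delimited(detection_path) if detection_path else None
    bead_count = _read_delimited(beadcount_path) if beadcount_path else None
    return BetaMatrix(beta=beta, detection_p=detection_p, bead_count=bead_count)


def write_beta_matrix(bm: BetaMatrix, path: str | Path, sep: str = "\t") -> None:
    bm.beta.to_csv(path, sep=sep, index_label="site_id")


# ---------------------------------------------------------------------------
# SampleSheet


@dataclass
class SampleSheet:
    """Per-sample metadata: cohort, reported ethnicity/sex, free covariates."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "dataset_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample sheet missing required column(s): {missing}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    @property
    def covariate_names(self) -> list[str]:
        fixed = {"sample_id", "dataset_id", "reported_ethnicity", "reported_sex"}
        return [c for c in self.data.columns if c not in fixed]

    def ethnicity(self) -> pd.Series:
        s = self.data.get("reported_ethnicity", pd.Series(index=self.data.index, dtype=object))
        return pd.Series(s.values, index=self.data["sample_id"].values, name="reported_ethnicity")

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        ids = set(sample_ids)
        return SampleSheet(self.data[self.data["sample_id"].isin(ids)].copy())


def normalize_ethnicity(values: Sequence) -> pd.Series:
    """Map reported ethnicity strings onto canonical labels via the alias table."""
    out = []
    for v in values:
        if pd.isna(v) or str(v).strip() == "":
            out.append(np.nan)
            continue
        key = str(v).strip().lower()
        if key in ETHNICITY_ALIASES:
            out.append(ETHNICITY_ALIASES[key])
        else:
            logger.warning("unrecognized ethnicity %r mapped to missing", v)
            out.append(np.nan)
    return pd.Series(out, dtype=object)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_delimited(path, index_col=None)
    if "reported_ethnicity" in df.columns:
        df["reported_ethnicity"] = normalize_ethnicity(df["reported_ethnicity"]).values
    if "reported_sex" in df.columns:
        sex = df["reported_sex"].astype(object).map(
            lambda v: np.nan
            if pd.isna(v) or str(v).strip() == ""
            else {"m": "M", "male": "M", "f": "F", "female": "F"}.get(
                str(v).strip().lower(), np.nan
            )
        )
        df["reported_sex"] = sex
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SiteAnnotation


@dataclass
class SiteAnnotation:
    """Per-site manifest: probe class/design, genomic context, QC and genetic flags."""

    data: pd.DataFrame

    REQUIRED = (
        "site_id",
        "probe_class",
        "design_type",
        "chromosome",
        "island_relation",
        "on_epic",
        "cross_hybridizing",
        "nonvariable",
        "snp_in_probe",
        "mqtl",
    )
    BOOL_COLS = ("on_epic", "cross_hybridizing", "nonvariable", "snp_in_probe", "mqtl")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"annotation missing required column(s): {missing}")
        df = self.data.copy()
        if df["site_id"].duplicated().any():
            raise ValueError("duplicate site_id in annotation")
        bad_class = set(df["probe_class"].unique()) - {"CpG", "SNP"}
        if bad_class:
            raise ValueError(f"unknown probe_class value(s): {sorted(bad_class)}")
        bad_design = set(df["design_type"].unique()) - {"I", "II"}
        if bad_design:
            raise ValueError(f"unknown design_type value(s): {sorted(bad_design)}")
        df["chromosome"] = df["chromosome"].astype(str)
        bad_chrom = set(df["chromosome"].unique()) - set(CHROMOSOMES)
        if bad_chrom:
            raise ValueError(f"unknown chromosome value(s): {sorted(bad_chrom)}")
        bad_island = set(df["island_relation"].unique()) - set(ISLAND_RELATIONS)
        if bad_island:
            raise ValueError(f"unknown island_relation value(s): {sorted(bad_island)}")
        for c in self.BOOL_COLS:
            df[c] = df[c].astype(bool)
        if "dist_to_variant" not in df.columns:
            df["dist_to_variant"] = np.nan
        df["dist_to_variant"] = pd.to_numeric(df["dist_to_variant"], errors="coerce")
        if (df["dist_to_variant"].dropna() < 0).any():
            raise ValueError("dist_to_variant must be non-negative")
        self.data = df.set_index("site_id", drop=False)

    @property
    def site_ids(self) -> pd.Index:
        return self.data.index

    def for_sites(self, sites: Iterable[str]) -> pd.DataFrame:
        sites = pd.Index(sites)
        unknown = sites.difference(self.data.index)
        if len(unknown):
            raise KeyError(f"sites not in annotation: {list(unknown[:5])}")
        return self.data.loc[sites]


def read_annotation(path: str | Path) -> SiteAnnotation:
    df = _read_delimited(path, index_col=None)
    return SiteAnnotation(df)


def write_annotation(ann: SiteAnnotation, path: str | Path) -> None:
    ann.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FittedClassifier


@dataclass
class FittedClassifier:
    """A fitted penalized multinomial ethnicity model on the beta scale.

    ``coefficients`` has one row per class (in ``classes`` order) and one
    column per entry of ``model_sites``; linear predictors are
    ``intercepts[c] + coefficients[c] @ x`` on raw beta values.
    """

    classes: list[str]
    intercepts: np.ndarray
    coefficients: np.ndarray
    model_sites: list[str]
    alpha: float
    lam: float
    preprocessing_record: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n_classes, n_sites = len(self.classes), len(self.model_sites)
        if self.intercepts.shape != (n_classes,):
            raise ValueError("intercepts not aligned to classes")
        if self.coefficients.shape != (n_classes, n_sites):
            raise ValueError("coefficients not aligned to classes x model_sites")

    @property
    def selected_sites(self) -> list[str]:
        """Sites with a nonzero coefficient in at least one class."""
        mask = (self.coefficients != 0).any(axis=0)
        return [s for s, m in zip(self.model_sites, mask) if m]


def save_model(model: FittedClassifier, path: str | Path) -> None:
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "classes": list(model.classes),
        "intercepts": model.intercepts.tolist(),
        "coefficients": model.coefficients.tolist(),
        "model_sites": list(model.model_sites),
        "alpha": model.alpha,
        "lambda": model.lam,
        "preprocessing_record": model.preprocessing_record,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> FittedClassifier:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"model file is not valid JSON (truncated or tampered?): {exc}")
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {version!r} not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    return FittedClassifier(
        classes=payload["classes"],
        intercepts=np.asarray(payload["intercepts"], dtype=float),
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        model_sites=payload["model_sites"],
        alpha=payload["alpha"],
        lam=payload["lambda"],
        preprocessing_record=payload.get("preprocessing_record", []),
    )


# ---------------------------------------------------------------------------
# PredictionResult


@dataclass
class PredictionResult:
    """Per-sample class probabilities and the final thresholded call."""

    sample_id: str
    prob_african: float
    prob_asian: float
    prob_caucasian: float
    predicted: str
    threshold: float

    def __post_init__(self) -> None:
        probs = (self.prob_african, self.prob_asian, self.prob_caucasian)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("class probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError(f"class probabilities sum to {sum(probs):.9f}, not 1")
        if self.predicted not in CLASSES + (AMBIGUOUS,):
            raise ValueError(f"unknown predicted label {self.predicted!r}")

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([self.prob_african, self.prob_asian, self.prob_caucasian])


def predictions_to_frame(results: Sequence[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "prob_African": [r.prob_african for r in results],
            "prob_Asian": [r.prob_asian for r in results],
            "prob_Caucasian": [r.prob_caucasian for r in results],
            "predicted": [r.predicted for r in results],
            "threshold": [r.threshold for r in results],
        }
    )


def write_predictions(results: Sequence[PredictionResult], path: str | Path) -> None:
    predictions_to_frame(results).to_csv(path, index=False)
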