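import numpy as np
import pandas as pd
import pytest

from methylancestry.io import BetaMatrix, SampleSheet, SiteAnnotation
from methylancestry.simulate import SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def tiny_sim():
    """Small 2-cohort simulation for fast unit tests; 7 planted failed-detection sites."""
    cfg = SimulationConfig(
        seed=7,
        n_snp_probes=30,
        n_mqtl_cpgs=60,
        n_background_cpgs=900,
        n_nonvariable_cpgs=40,
        n_crosshyb_cpgs=30,
        n_sexchr_cpgs=30,
        n_offepic_cpgs=20,
        n_cohorts=2,
        cohort_sizes=(25, 25),
        n_failed_detection_sites=7,
        n_low_bead_sites=5,
        n_sporadic_failures=0,  # 1 failure of 50 samples would exceed the 1% cutoff
        n_noise_samples=1,
        n_sex_mislabels=1,
    )
    return (cfg,) + simulate_cohorts(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions (5 cohorts, 59 SNP probes, fst 0.15), seed 1."""
    cfg = SimulationConfig(seed=1)
    return (cfg,) + simulate_cohorts(cfg)


def make_annotation(site_ids, **overrides) -> SiteAnnotation:
    """Minimal all-CpG annotation; columns overridable per test."""
    n = len(site_ids)
    base = {
        "site_id": list(site_ids),
        "probe_class": ["CpG"] * n,
        "design_type": ["II"] * n,
        "chromosome": ["1"] * n,
        "island_relation": ["OpenSea"] * n,
        "on_epic": [True] * n,
        "cross_hybridizing": [False] * n,
        "nonvariable": [False] * n,
        "snp_in_probe": [False] * n,
        "dist_to_variant": [np.nan] * n,
        "mqtl": [False] * n,
    }
    base.update(overrides)
    return SiteAnnotation(pd.DataFrame(base))


def make_beta(values, site_ids=None, sample_ids=None, **layers) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    site_ids = site_ids or [f"cg{i:03d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    frames = {
        k: pd.DataFrame(np.asarray(v, dtype=float), index=site_ids, columns=sample_ids)
        for k, v in layers.items()
    }
    return BetaMatrix(
        beta=pd.DataFrame(values, index=site_ids, columns=sample_ids), **frames
    )


def make_sheet(sample_ids, **cols) -> SampleSheet:
    base = {"sample_id": list(sample_ids), "dataset_id": ["D1"] * len(sample_ids)}
    base.update(cols)
    return SampleSheet(pd.DataFrame(base))
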