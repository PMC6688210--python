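"""Seeded generator of population-structured methylation cohorts.

The generator emulates the genetic architecture known to drive ancestry
signal on Illumina methylation arrays: SNP probes whose beta values cluster
trimodally by genotype, mQTL CpGs whose means shift with the local allele
count, a large background of non-genetic CpGs, admixed individuals,
cohort-level batch effects, sex-chromosome signal, and planted QC defects
(failed detections, low bead counts, uniform-noise outlier samples, sex
mislabels). Allele frequencies follow the Balding-Nichols model: for each
variant an ancestral frequency p ~ Uniform(0.1, 0.9) is drawn, and each
population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), so F (a fixation
index, FST) controls how differentiated the three populations are.

Every random draw comes from a single numpy Generator seeded by
``SimulationConfig.seed``; identical configs reproduce identical cohorts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    CLASSES,
    BetaMatrix,
    SampleSheet,
    SiteAnnotation,
    write_annotation,
    write_beta_matrix,
    write_sample_sheet,
)

#: Genotype-to-beta cluster means for SNP probes (0/1/2 alternate alleles).
SNP_BETA_MEANS = np.array([0.05, 0.5, 0.95])
SNP_BETA_SD = 0.03

#: Sex-chromosome methylation means: (male, female).
CHRY_MEANS = {"M": 0.8, "F": 0.1}
CHRX_MEANS = {"M": 0.8, "F": 0.5}
SEXCHR_SD = 0.03


@dataclass
class SimulationConfig:
    """Study conditions for a simulated multi-cohort placental methylome."""

    n_populations: int = 3
    fst: float = 0.15
    n_snp_probes: int = 59
    n_mqtl_cpgs: int = 200
    n_background_cpgs: int = 5000
    n_nonvariable_cpgs: int = 300
    n_crosshyb_cpgs: int = 150
    n_sexchr_cpgs: int = 60
    n_offepic_cpgs: int = 100
    mqtl_effect: float = 0.15  # per-allele shift on the beta scale
    n_cohorts: int = 5
    cohort_sizes: tuple[int, ...] | None = None  # default 30 per cohort
    population_weights: tuple[float, ...] = (0.25, 0.25, 0.50)
    batch_sd: float = 0.3  # logit scale
    admixed_fraction: float = 0.1
    dirichlet_alpha: float = 1.0
    noise_sd: float = 0.05  # logit scale
    nonvariable_noise_sd: float = 0.005
    # planted QC defects
    n_failed_detection_sites: int = 25
    n_low_bead_sites: int = 15
    n_sporadic_failures: int = 50  # isolated failing measurements (kept, imputed)
    n_noise_samples: int = 2
    n_sex_mislabels: int = 2
    ambiguity_threshold: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie strictly in (0, 1)")
        if self.n_populations != len(CLASSES):
            raise ValueError(f"n_populations must be {len(CLASSES)}")
        if self.cohort_sizes is None:
            self.cohort_sizes = tuple([30] * self.n_cohorts)
        if len(self.cohort_sizes) != self.n_cohorts:
            raise ValueError("cohort_sizes length must equal n_cohorts")
        counts = (
            self.n_failed_detection_sites
            + self.n_low_bead_sites
        )
        if counts > self.n_background_cpgs:
            raise ValueError("more planted defect sites than background CpGs")
        if self.n_noise_samples + self.n_sex_mislabels > sum(self.cohort_sizes):
            raise ValueError("more planted defect samples than samples")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated cohort set."""

    samples: pd.DataFrame  # admixture q's, true label, sex, cohort, defect flags
    sites: pd.DataFrame  # role and planted-defect flags per site
    genotypes: pd.DataFrame  # variant sites x samples, values in {0,1,2}
    allele_freqs: pd.DataFrame  # variant sites x populations


def draw_allele_frequencies(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Balding-Nichols population allele frequencies for all variant sites."""
    if not 0 < config.fst < 1:
        raise ValueError("fst must lie strictly in (0, 1)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_var = config.n_snp_probes + config.n_mqtl_cpgs
    ancestral = rng.uniform(0.1, 0.9, size=n_var)
    f = config.fst
    shape1 = ancestral * (1 - f) / f
    shape2 = (1 - ancestral) * (1 - f) / f
    freqs = rng.beta(
        shape1[:, None], shape2[:, None], size=(n_var, config.n_populations)
    )
    ids = _variant_ids(config)
    out = pd.DataFrame(freqs, index=ids, columns=list(CLASSES))
    out.insert(0, "ancestral", ancestral)
    return out


def _variant_ids(config: SimulationConfig) -> list[str]:
    snp = [f"rs{i:07d}" for i in range(config.n_snp_probes)]
    mqtl = [f"cg{i:07d}" for i in range(config.n_mqtl_cpgs)]
    return snp + mqtl


def _logit_shift_for_beta_shift(mu: np.ndarray, shift: float) -> np.ndarray:
    """Per-site logit increment moving the site mean by `shift` per allele."""
    target = np.clip(mu + shift, 1e-4, 1 - 1e-4)
    return logit(target) - logit(np.clip(mu, 1e-4, 1 - 1e-4))


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[BetaMatrix, SampleSheet, SiteAnnotation, SyntheticTruth]:
    """Simulate beta/detection/bead layers, sample sheet, manifest and truth."""
    rng = np.random.default_rng(config.seed)
    n_samples = int(sum(config.cohort_sizes))

    # --- samples: cohort, admixture, sex -----------------------------------
    cohorts = np.repeat(
        [f"C{i + 1}" for i in range(config.n_cohorts)], config.cohort_sizes
    )
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    q = np.zeros((n_samples, 3))
    admixed = rng.random(n_samples) < config.admixed_fraction
    pure_pop = rng.choice(3, size=n_samples, p=np.asarray(config.population_weights))
    for i in range(n_samples):
        if admixed[i]:
            q[i] = rng.dirichlet([config.dirichlet_alpha] * 3)
        else:
            q[i, pure_pop[i]] = 1.0
    sex = np.where(rng.random(n_samples) < 0.5, "M", "F")
    qmax = q.max(axis=1)
    true_label = np.where(
        qmax >= config.ambiguity_threshold,
        np.asarray(CLASSES)[q.argmax(axis=1)],
        "Mixed",
    )
    reported = np.asarray(CLASSES)[q.argmax(axis=1)]  # people self-report the majority

    # --- genotypes at variant sites ----------------------------------------
    freqs = draw_allele_frequencies(config, seed=config.seed)
    pop_freqs = freqs[list(CLASSES)].to_numpy()  # variants x pops
    dosage_p = pop_freqs @ q.T  # variants x samples
    genotypes = rng.binomial(2, dosage_p)

    n_snp = config.n_snp_probes
    snp_ids = freqs.index[:n_snp].tolist()
    mqtl_ids = freqs.index[n_snp:].tolist()

    # --- per-site blocks ----------------------------------------------------
    blocks: list[np.ndarray] = []
    site_ids: list[str] = []
    roles: list[str] = []

    # SNP probes: trimodal clusters by genotype, no batch/noise beyond cluster sd
    snp_beta = SNP_BETA_MEANS[genotypes[:n_snp]] + rng.normal(
        0, SNP_BETA_SD, size=(n_snp, n_samples)
    )
    blocks.append(np.clip(snp_beta, 0, 1))
    site_ids += snp_ids
    roles += ["snp_probe"] * n_snp

    batch_codes = pd.factorize(cohorts)[0]

    def _batch(n_sites: int) -> np.ndarray:
        per_cohort = rng.normal(0, config.batch_sd, size=(n_sites, config.n_cohorts))
        return per_cohort[:, batch_codes]

    # mQTL CpGs: genotype-shifted means on the logit scale
    mu_mqtl = rng.uniform(0.25, 0.75, size=config.n_mqtl_cpgs)
    shift = _logit_shift_for_beta_shift(mu_mqtl, config.mqtl_effect)
    lin = (
        logit(mu_mqtl)[:, None]
        + genotypes[n_snp:] * shift[:, None]
        + _batch(config.n_mqtl_cpgs)
        + rng.normal(0, config.noise_sd, size=(config.n_mqtl_cpgs, n_samples))
    )
    blocks.append(expit(lin))
    site_ids += mqtl_ids
    roles += ["mqtl"] * config.n_mqtl_cpgs

    def _background_mu(n: int) -> np.ndarray:
        comp = rng.choice(3, size=n, p=[0.4, 0.2, 0.4])
        params = [(0.5, 5.0), (5.0, 5.0), (5.0, 0.5)]
        a = np.array([params[c][0] for c in comp])
        b = np.array([params[c][1] for c in comp])
        return np.clip(rng.beta(a, b), 1e-3, 1 - 1e-3)

    def _plain_block(n: int, noise_sd: float, with_batch: bool = True) -> np.ndarray:
        mu = _background_mu(n)
        lin = logit(mu)[:, None] + rng.normal(0, noise_sd, size=(n, n_samples))
        if with_batch:
            lin = lin + _batch(n)
        return expit(lin)

    next_cg = config.n_mqtl_cpgs
    for role, count, noise_sd, with_batch in (
        ("background", config.n_background_cpgs, config.noise_sd, True),
        ("nonvariable", config.n_nonvariable_cpgs, config.nonvariable_noise_sd, False),
        ("crosshyb", config.n_crosshyb_cpgs, config.noise_sd, True),
        ("offepic", config.n_offepic_cpgs, config.noise_sd, True),
    ):
        blocks.append(_plain_block(count, noise_sd, with_batch))
        site_ids += [f"cg{next_cg + i:07d}" for i in range(count)]
        next_cg += count
        roles += [role] * count

    # sex-chromosome sites: half Y, half X
    n_sex = config.n_sexchr_cpgs
    n_y = n_sex // 2
    sex_means = np.empty((n_sex, n_samples))
    is_male = sex == "M"
    sex_means[:n_y] = np.where(is_male, CHRY_MEANS["M"], CHRY_MEANS["F"])
    sex_means[n_y:] = np.where(is_male, CHRX_MEANS["M"], CHRX_MEANS["F"])
    blocks.append(np.clip(sex_means + rng.normal(0, SEXCHR_SD, size=sex_means.shape), 0, 1))
    site_ids += [f"cg{next_cg + i:07d}" for i in range(n_sex)]
    next_cg += n_sex
    roles += ["sexchr_Y"] * n_y + ["sexchr_X"] * (n_sex - n_y)

    beta = np.vstack(blocks)
    roles = np.asarray(roles)
    site_index = pd.Index(site_ids)

    # --- QC defect layers ---------------------------------------------------
    detection_p = rng.uniform(0, 0.005, size=beta.shape)
    bead_count = rng.integers(8, 25, size=beta.shape).astype(float)

    bg_positions = np.flatnonzero(roles == "background")
    defect_pool = rng.permutation(bg_positions)
    failed_det_sites = np.sort(defect_pool[: config.n_failed_detection_sites])
    low_bead_sites = np.sort(
        defect_pool[
            config.n_failed_detection_sites : config.n_failed_detection_sites
            + config.n_low_bead_sites
        ]
    )
    # fail strictly more than 1% of samples at each planted-defect site
    n_fail = max(2, int(np.ceil(0.03 * n_samples)))
    planted_coords: list[tuple[int, int]] = []
    for s in failed_det_sites:
        cols = rng.choice(n_samples, size=n_fail, replace=False)
        detection_p[s, cols] = rng.uniform(0.02, 0.5, size=n_fail)
        planted_coords += [(s, c) for c in cols]
    for s in low_bead_sites:
        cols = rng.choice(n_samples, size=n_fail, replace=False)
        bead_count[s, cols] = rng.integers(0, 3, size=n_fail)
        planted_coords += [(s, c) for c in cols]
    # sporadic single-measurement failures on clean background sites (kept,
    # masked to missing and later imputed)
    sporadic_pool = defect_pool[
        config.n_failed_detection_sites + config.n_low_bead_sites :
    ]
    n_sporadic = min(config.n_sporadic_failures, len(sporadic_pool))
    sporadic_sites = sporadic_pool[:n_sporadic]
    for s in sporadic_sites:
        c = int(rng.integers(n_samples))
        detection_p[s, c] = rng.uniform(0.02, 0.5)

    # noise samples: uniform betas across every site
    defect_samples = rng.permutation(n_samples)
    noise_samples = np.sort(defect_samples[: config.n_noise_samples])
    beta[:, noise_samples] = rng.uniform(0, 1, size=(beta.shape[0], len(noise_samples)))
    # sex mislabels: flip the *reported* sex only
    mislabeled = np.sort(
        defect_samples[
            config.n_noise_samples : config.n_noise_samples + config.n_sex_mislabels
        ]
    )
    reported_sex = sex.copy()
    reported_sex[mislabeled] = np.where(sex[mislabeled] == "M", "F", "M")

    # --- annotation ---------------------------------------------------------
    n_sites = len(site_ids)
    autosomes = rng.choice([str(i) for i in range(1, 23)], size=n_sites)
    chromosome = np.asarray(autosomes, dtype=object)
    chromosome[roles == "sexchr_Y"] = "Y"
    chromosome[roles == "sexchr_X"] = "X"
    island = rng.choice(
        ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"],
        size=n_sites,
        p=[0.25, 0.1, 0.1, 0.05, 0.05, 0.45],
    )
    dist = np.full(n_sites, np.nan)
    dist[: n_snp] = 0.0
    dist[roles == "mqtl"] = rng.choice(
        [0, 1, 2, 5, 10, 50], size=(roles == "mqtl").sum(), p=[0.3, 0.1, 0.1, 0.2, 0.15, 0.15]
    )
    far = rng.random(n_sites) < 0.05
    far &= roles == "background"
    dist[far] = rng.integers(100, 10_000, size=far.sum()).astype(float)

    ann = SiteAnnotation(
        pd.DataFrame(
            {
                "site_id": site_ids,
                "probe_class": np.where(roles == "snp_probe", "SNP", "CpG"),
                "design_type": rng.choice(["I", "II"], size=n_sites, p=[0.3, 0.7]),
                "chromosome": chromosome,
                "island_relation": island,
                "on_epic": roles != "offepic",
                "cross_hybridizing": roles == "crosshyb",
                "nonvariable": roles == "nonvariable",
                "snp_in_probe": (roles == "mqtl") & (dist == 0),
                "dist_to_variant": dist,
                "mqtl": roles == "mqtl",
            }
        )
    )

    bm = BetaMatrix(
        beta=pd.DataFrame(np.clip(beta, 0, 1), index=site_index, columns=sample_ids),
        detection_p=pd.DataFrame(detection_p, index=site_index, columns=sample_ids),
        bead_count=pd.DataFrame(bead_count, index=site_index, columns=sample_ids),
    )

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "dataset_id": cohorts,
                "reported_ethnicity": reported,
                "reported_sex": reported_sex,
                "gestational_age": np.round(rng.normal(38, 2, size=n_samples), 1),
                "array_row": rng.integers(1, 7, size=n_samples),
            }
        )
    )

    samples_truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": cohorts,
            "q_African": q[:, 0],
            "q_Asian": q[:, 1],
            "q_Caucasian": q[:, 2],
            "true_label": true_label,
            "sex": sex,
            "is_noise": np.isin(np.arange(n_samples), noise_samples),
            "sex_mislabeled": np.isin(np.arange(n_samples), mislabeled),
        }
    )
    sites_truth = pd.DataFrame(
        {
            "site_id": site_ids,
            "role": roles,
            "planted_failed_detection": np.isin(np.arange(n_sites), failed_det_sites),
            "planted_low_bead": np.isin(np.arange(n_sites), low_bead_sites),
            "planted_sporadic_failure": np.isin(np.arange(n_sites), sporadic_sites),
        }
    )
    truth = SyntheticTruth(
        samples=samples_truth,
        sites=sites_truth,
        genotypes=pd.DataFrame(genotypes, index=freqs.index, columns=sample_ids),
        allele_freqs=freqs,
    )
    return bm, sheet, ann, truth


def write_simulation(
    outdir: str | Path,
    bm: BetaMatrix,
    sheet: SampleSheet,
    ann: SiteAnnotation,
    truth: SyntheticTruth,
) -> None:
    """Write a simulated cohort set as plain-text files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(bm, outdir / "betas.tsv")
    bm.detection_p.to_csv(outdir / "detection_p.tsv", sep="\t", index_label="site_id")
    bm.bead_count.to_csv(outdir / "beadcounts.tsv", sep="\t", index_label="site_id")
    write_sample_sheet(sheet, outdir / "samplesheet.csv")
    write_annotation(ann, outdir / "annotation.csv")
    truth.samples.to_csv(outdir / "truth_samples.csv", index=False)
    truth.sites.to_csv(outdir / "truth_sites.csv", index=False)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["cohort_sizes"] = list(config.cohort_sizes)
    d["population_weights"] = list(config.population_weights)
    return d
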