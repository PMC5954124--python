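"""Synthetic cohort generator.

Generates the three inputs the analysis chain consumes — genotypes with block
LD, discovery GWAS summary statistics, and an ERP/clinical phenotype table —
with the statistical structure the downstream stages assume: a latent
three-cluster ERP mixture whose "globally impaired" cluster membership depends
on a true polygenic score, and a configurable mediation structure
PRS -> impaired-cluster membership -> positive-symptom severity.

Design of the genotype model: haplotypes are Gaussian-copula draws with
AR(1) correlation inside contiguous LD blocks (zero across blocks),
thresholded to alleles at the minor-allele-frequency quantile; a genotype is
the sum of two independent haplotypes, so Hardy-Weinberg equilibrium holds by
construction.

All randomness flows from one seed through named substreams (variant
metadata / genotypes / per-trait summary statistics / phenotypes) so each
stage can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit
from scipy.stats import norm

from .containers import (
    ERP_MEASURES,
    IMPAIRMENT_DIRECTIONS,
    ConfigurationError,
    GenotypeMatrix,
    validate_sumstats,
)

# substream labels -> spawn keys under the master seed
_STREAM_VARIANTS = 0
_STREAM_GENOTYPES = 1
_STREAM_SUMSTATS = 2
_STREAM_PHENOTYPES = 3

_CHUNK_BLOCKS = 256  # LD blocks generated per chunk (memory control)

_NONAMBIGUOUS_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                       ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

#: Default per-cluster ERP means, rows = (globally impaired, intermediate,
#: high functioning), columns = ERP_MEASURES. Raw units (%, uV, uV, uV, uV, ms).
DEFAULT_CLUSTER_MEANS = np.array([
    [95.0, 1.0, 3.2, 1.6, 2.6, 405.0],
    [58.0, 1.9, 5.6, 3.0, 4.8, 362.0],
    [25.0, 2.8, 8.0, 4.4, 7.2, 325.0],
])

DEFAULT_CLUSTER_SDS = np.array([
    [17.0, 0.38, 1.0, 0.60, 0.95, 21.0],
    [16.0, 0.42, 1.1, 0.70, 1.05, 20.0],
    [14.0, 0.46, 1.2, 0.75, 1.15, 18.0],
])

#: Cluster-conditional diagnosis probabilities (SCZ, BPD, control),
#: matching the observed margins of the impaired / non-impaired groups.
DIAG_PROBS_IMPAIRED = np.array([0.483, 0.433, 0.083]) / 0.999
DIAG_PROBS_NONIMPAIRED = np.array([0.331, 0.297, 0.372])

#: Default effective discovery-GWAS sample sizes per trait (cases+controls
#: scale of the consortium discovery sets used for each score).
DEFAULT_DISCOVERY_N = {
    "scz": 77_080,
    "bpd": 16_731,
    "college": 101_069,
    "intelligence": 12_411,
}


@dataclass
class CovariateSpec:
    """Distributions of the non-genetic covariates."""

    age_mean: float = 40.0
    age_sd: float = 13.0
    age_range: tuple[float, float] = (18.0, 65.0)
    p_female: float = 0.5
    #: smoking probability by latent group (impaired, non-impaired)
    p_smoker: tuple[float, float] = (0.42, 0.24)
    #: log-scale parameters of the chlorpromazine-equivalent dose (cases only)
    cpz_log_mean: float = 5.5
    cpz_log_sd: float = 0.9


@dataclass
class MediationTruth:
    """Generating coefficients of the mediation structure.

    Mediator model (logistic, membership in the impaired cluster):
    ``logit P(M=1) = b0 + b1 * PRS_z + b2 . (age_z, sex_female)``.

    Outcome model (PANSS positive, cases):
    ``Y = t0 + t1 * PRS_z + t2 * M + t3 * PRS_z * M + t4 . (age_z, sex_female)
    + Normal(0, outcome_sd)``.
    """

    b0: float = -1.75
    b1: float = 0.5
    b2: tuple[float, float] = (0.0, 0.0)
    t0: float = 16.0
    t1: float = 0.5
    t2: float = 4.0
    t3: float = 0.0
    t4: tuple[float, float] = (0.0, 0.0)
    outcome_sd: float = 7.0


@dataclass
class SimulationConfig:
    """Full specification of one synthetic cohort.

    Defaults emulate the study conditions: 383 European-ancestry samples with
    a 136/122/125 SCZ/BPD/control mix, a ~60-member globally impaired ERP
    cluster whose membership loads on the college-completion polygenic score,
    and PANSS-positive scores observed for 161 of the 258 cases.
    """

    n_samples: int = 383
    n_variants: int = 100_000
    ld_block_size: int = 50
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int | None = None  # default: min(500, n_variants // 10)
    causal_effect_sd: float = 0.05
    discovery_n: dict = field(default_factory=lambda: dict(DEFAULT_DISCOVERY_N))
    cluster_means: np.ndarray = field(default_factory=lambda: DEFAULT_CLUSTER_MEANS.copy())
    cluster_sds: np.ndarray = field(default_factory=lambda: DEFAULT_CLUSTER_SDS.copy())
    #: (intercept, PRS coefficient) of the impaired-membership logit; kept in
    #: sync with ``mediation_truth.b0/b1`` (single source of truth).
    cluster_logit: tuple[float, float] = (-1.75, 0.5)
    mediation_truth: MediationTruth = field(default_factory=MediationTruth)
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    missing_rate: float = 0.005
    seed: int = 0
    #: trait whose true polygenic score drives impaired-cluster membership
    cluster_trait: str = "college"
    #: fraction of cases with an observed PANSS-positive score (161/258)
    panss_fraction: float = 161 / 258
    ambiguous_fraction: float = 0.05
    position_spacing: int = 5_000
    diag_probs_impaired: np.ndarray = field(
        default_factory=lambda: DIAG_PROBS_IMPAIRED.copy())
    diag_probs_nonimpaired: np.ndarray = field(
        default_factory=lambda: DIAG_PROBS_NONIMPAIRED.copy())

    def __post_init__(self) -> None:
        self.cluster_means = np.asarray(self.cluster_means, dtype=float)
        self.cluster_sds = np.asarray(self.cluster_sds, dtype=float)
        if min(self.n_samples, self.n_variants, self.ld_block_size) <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_causal is None:
            self.n_causal = min(500, max(1, self.n_variants // 10))
        if not (0 <= self.n_causal <= self.n_variants):
            raise ConfigurationError("n_causal must lie in [0, n_variants]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.within_block_r < 1):
            raise ConfigurationError("within_block_r must lie in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.cluster_means.shape != (3, 6) or self.cluster_sds.shape != (3, 6):
            raise ConfigurationError("cluster_means and cluster_sds must be 3x6")
        if np.any(self.cluster_sds <= 0):
            raise ConfigurationError("cluster SDs must be positive")
        # cluster_logit is an alias for the mediator-model intercept/slope
        b0, b1 = self.cluster_logit
        if (b0, b1) != (self.mediation_truth.b0, self.mediation_truth.b1):
            self.mediation_truth = replace(self.mediation_truth, b0=b0, b1=b1)
        # impaired row must be strictly worse on every measure
        gi = self.cluster_means[0] * IMPAIRMENT_DIRECTIONS
        others = self.cluster_means[1:] * IMPAIRMENT_DIRECTIONS
        if not np.all(gi > others):
            raise ConfigurationError(
                "impaired cluster mean must be strictly worse than both other "
                "clusters on every measure under the impairment directions")

    def rng(self, *spawn_key: int) -> np.random.Generator:
        """Generator for one named substream under the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=spawn_key))

    @property
    def n_blocks(self) -> int:
        return math.ceil(self.n_variants / self.ld_block_size)

    @property
    def traits(self) -> list[str]:
        return list(self.discovery_n)


# ---------------------------------------------------------------------------
# variant metadata (shared by genotypes and summary statistics)

def _variant_metadata(config: SimulationConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Deterministic variant table and per-variant MAFs (substream 0)."""
    rng = config.rng(_STREAM_VARIANTS)
    m, bs = config.n_variants, config.ld_block_size
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    amb = rng.random(m) < config.ambiguous_fraction
    pick_non = rng.integers(0, len(_NONAMBIGUOUS_PAIRS), size=m)
    pick_amb = rng.integers(0, len(_AMBIGUOUS_PAIRS), size=m)
    refs = np.where(amb, [ _AMBIGUOUS_PAIRS[i][0] for i in pick_amb ],
                    [ _NONAMBIGUOUS_PAIRS[i][0] for i in pick_non ])
    alts = np.where(amb, [ _AMBIGUOUS_PAIRS[i][1] for i in pick_amb ],
                    [ _NONAMBIGUOUS_PAIRS[i][1] for i in pick_non ])

    # contiguous LD blocks mapped onto chromosomes 1..22; positions strictly
    # increasing within each chromosome
    block_of = np.arange(m) // bs
    nb = config.n_blocks
    chrom_per_block = 1 + (np.arange(nb) * 22) // nb
    chroms = chrom_per_block[block_of]
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chroms):
        idx = np.where(chroms == c)[0]
        pos[idx] = 1_000_000 + config.position_spacing * np.arange(idx.size)

    variants = pd.DataFrame({
        "chrom": chroms.astype(str),
        "pos": pos,
        "id": [f"rs{i + 1}" for i in range(m)],
        "ref": refs,
        "alt": alts,
    })
    return variants, mafs


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate an LD-blocked dosage matrix.

    Within each block of ``ld_block_size`` variants, latent haplotype normals
    follow an AR(1) process with lag-one correlation ``within_block_r``;
    blocks are independent. Alleles are the latent normal thresholded at the
    MAF quantile, genotypes the sum of two haplotypes, and missingness is
    applied uniformly at random at ``missing_rate``.
    """
    variants, mafs = _variant_metadata(config)
    rng = config.rng(_STREAM_GENOTYPES)
    n, m, bs = config.n_samples, config.n_variants, config.ld_block_size
    r = config.within_block_r
    thr = norm.ppf(mafs)

    dosages = np.empty((n, m), dtype=np.float32)
    m_padded = config.n_blocks * bs
    start = 0
    while start < config.n_blocks:
        nb = min(_CHUNK_BLOCKS, config.n_blocks - start)
        eps = rng.standard_normal((2 * n, nb, bs))
        if r > 0:
            eps[:, :, 0] /= math.sqrt(1.0 - r * r)
            z = lfilter([math.sqrt(1.0 - r * r)], [1.0, -r], eps, axis=-1)
        else:
            z = eps
        lo = start * bs
        hi = min(m, lo + nb * bs)
        zc = z.reshape(2 * n, nb * bs)[:, : hi - lo]
        hap = (zc < thr[lo:hi]).astype(np.int8)
        dosages[:, lo:hi] = (hap[:n] + hap[n:]).astype(np.float32)
        start += nb
    assert m_padded >= m

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosages[miss] = np.nan

    g = GenotypeMatrix(
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
        variants=variants,
        dosages=dosages,
    )
    return g


# ---------------------------------------------------------------------------
# discovery summary statistics

def true_effects(config: SimulationConfig, trait: str) -> np.ndarray:
    """Per-variant generating (true) effects for one discovery trait."""
    if trait not in config.discovery_n:
        raise ConfigurationError(
            f"unknown trait {trait!r}; configured traits: {config.traits}")
    if config.n_causal > config.n_variants:
        raise ConfigurationError("n_causal must not exceed n_variants")
    t_idx = config.traits.index(trait)
    rng = config.rng(_STREAM_SUMSTATS, t_idx, 0)
    beta = np.zeros(config.n_variants)
    causal = rng.choice(config.n_variants, size=config.n_causal, replace=False)
    beta[causal] = rng.normal(0.0, config.causal_effect_sd, size=config.n_causal)
    return beta


def simulate_summary_stats(config: SimulationConfig, trait: str) -> pd.DataFrame:
    """Simulate a discovery GWAS for one trait.

    Reported effects are the true effects plus sampling noise at the standard
    error implied by the effective discovery sample size,
    ``se = 1 / sqrt(2 * N * maf * (1 - maf))``; p-values are two-sided normal
    tail probabilities of the reported z-score.
    """
    beta_true = true_effects(config, trait)  # validates the trait label
    variants, mafs = _variant_metadata(config)
    t_idx = config.traits.index(trait)
    rng = config.rng(_STREAM_SUMSTATS, t_idx, 1)

    n_disc = float(config.discovery_n[trait])
    se = 1.0 / np.sqrt(2.0 * n_disc * mafs * (1.0 - mafs))
    effect = beta_true + se * rng.standard_normal(config.n_variants)
    z = effect / se
    p = np.minimum(2.0 * norm.sf(np.abs(z)), 1.0)
    p = np.maximum(p, np.finfo(float).tiny)  # keep p in (0, 1]

    ss = variants.rename(columns={"alt": "effect_allele", "ref": "other_allele"})
    ss = ss[["chrom", "pos", "id", "effect_allele", "other_allele"]].copy()
    ss["effect"] = effect
    ss["se"] = se
    ss["p"] = p
    return validate_sumstats(ss)


# ---------------------------------------------------------------------------
# phenotypes

def simulate_phenotypes_from_prs(
    prs_z: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Phenotype table given a standardized true polygenic score.

    This is the phenotype core of the generator, exposed separately so that
    large-sample Monte-Carlo runs (e.g. computing the generating value of a
    mediation estimand) can bypass genotype simulation.
    """
    n = prs_z.shape[0]
    cov = config.covariate_spec
    truth = config.mediation_truth

    age = np.clip(rng.normal(cov.age_mean, cov.age_sd, n), *cov.age_range)
    age_z = (age - cov.age_mean) / cov.age_sd
    female = rng.random(n) < cov.p_female
    cvec = np.column_stack([age_z, female.astype(float)])

    # latent cluster: impaired membership from the logistic mediator model,
    # the rest split evenly between intermediate and high-functioning
    lp = truth.b0 + truth.b1 * prs_z + cvec @ np.asarray(truth.b2)
    gi = rng.random(n) < expit(lp)
    other = rng.integers(1, 3, size=n)
    cluster = np.where(gi, 0, other)

    means = config.cluster_means[cluster]
    sds = config.cluster_sds[cluster]
    erp = rng.normal(means, sds)
    erp[:, 0] = np.maximum(erp[:, 0], 0.0)  # P50 ratio is non-negative

    probs = np.where(gi[:, None], config.diag_probs_impaired,
                     config.diag_probs_nonimpaired)
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    diag_idx = (u[:, None] > cum).sum(axis=1)
    diagnosis = np.array(["SCZ", "BPD", "control"])[diag_idx]
    is_case = diag_idx < 2

    p_smoke = np.where(gi, cov.p_smoker[0], cov.p_smoker[1])
    smoker = rng.random(n) < p_smoke

    cpz = np.full(n, np.nan)
    cpz[is_case] = rng.lognormal(cov.cpz_log_mean, cov.cpz_log_sd, is_case.sum())

    noise = rng.normal(0.0, truth.outcome_sd, n)
    panss = (truth.t0 + truth.t1 * prs_z + truth.t2 * gi
             + truth.t3 * prs_z * gi + cvec @ np.asarray(truth.t4) + noise)
    panss = np.where(is_case, panss, np.nan)
    has_panss = rng.random(n) < config.panss_fraction
    panss = np.where(is_case & has_panss, panss, np.nan)

    table = pd.DataFrame({
        "diagnosis": diagnosis,
        **{m: erp[:, j] for j, m in enumerate(ERP_MEASURES)},
        "panss_positive": panss,
        "age": age,
        "sex": np.where(female, "F", "M"),
        "smoker": np.where(smoker, "yes", "no"),
        "cpz_dose": cpz,
        "true_cluster": cluster,
        "true_prs": prs_z,
    })
    return table


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    sumstats: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate the phenotype/covariate table for a genotyped cohort.

    The true polygenic score of ``config.cluster_trait`` (dosages weighted by
    the generating effects, standardized) drives impaired-cluster membership;
    the six ERP measures are drawn from the member cluster's normal
    distributions; diagnosis is cluster-conditional; PANSS positive follows
    the generating mediation outcome model and is observed for a
    ``panss_fraction`` subset of cases, missing completely at random.

    ``sumstats`` is accepted for interface symmetry and dimension checking
    only — phenotypes depend on the *true* effects, not the noisy reported
    ones.
    """
    if genotypes.n_samples != config.n_samples:
        raise ConfigurationError("genotype matrix does not match config.n_samples")
    if sumstats is not None and len(sumstats) != genotypes.n_variants:
        raise ConfigurationError("summary statistics do not match genotype variants")

    beta = true_effects(config, config.cluster_trait)
    prs = genotypes.imputed_dosages() @ beta
    sd = prs.std()
    prs_z = (prs - prs.mean()) / sd if sd > 0 else np.zeros_like(prs)

    rng = config.rng(_STREAM_PHENOTYPES)
    table = simulate_phenotypes_from_prs(prs_z, config, rng)
    table.index = pd.Index(genotypes.sample_ids, name="sample_id")
    return table


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper: genotypes, per-trait summary stats, phenotypes."""
    g = simulate_genotypes(config)
    sumstats = {t: simulate_summary_stats(config, t) for t in config.traits}
    pheno = simulate_phenotypes(g, sumstats[config.cluster_trait], config)
    return g, sumstats, pheno
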