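"""Genotype quality control and ancestry principal components.

Filter order follows common array-QC practice: variant filters (chromosome,
call rate, MAF, Hardy-Weinberg), then sample filters (missingness,
heterozygosity outliers), then relatedness exclusion on an LD-pruned panel,
then PCA of the standardized genotype matrix. The report records every
removal with its reason so counts always reconcile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .containers import AncestryPCs, ConfigurationError, GenotypeMatrix


@dataclass
class QCThresholds:
    """Variant- and sample-level QC thresholds.

    Defaults: drop variants with MAF < 0.05, call rate < 98%, or HWE exact
    P < 1e-6; drop samples with > 5% missing genotypes or a heterozygosity
    rate more than 3 SD from the sample mean; flag one of each pair with
    PI_HAT > 0.125; keep the top 3 ancestry PCs.
    """

    maf_min: float = 0.05
    call_rate_min: float = 0.98
    hwe_p_min: float = 1e-6
    sample_missing_max: float = 0.05
    het_sd: float = 3.0
    relatedness_max: float = 0.125
    n_pcs: int = 3

    def __post_init__(self) -> None:
        ok = (0 <= self.maf_min <= 0.5 and 0 < self.call_rate_min <= 1
              and 0 < self.hwe_p_min < 1 and 0 <= self.sample_missing_max < 1
              and self.het_sd > 0 and 0 < self.relatedness_max <= 1
              and self.n_pcs >= 1)
        if not ok:
            raise ConfigurationError("QC threshold out of valid range")


@dataclass
class QCReport:
    """Itemized record of removed variants and samples."""

    removed_variants: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    n_variants_before: int = 0
    n_variants_after: int = 0
    n_samples_before: int = 0
    n_samples_after: int = 0
    notes: list[str] = field(default_factory=list)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities that are no larger than that of the
    observed heterozygote count. Monomorphic variants return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or (n_AA + n_Aa + n_aa) == 0:
        raise ConfigurationError("genotype counts must be non-negative, not all zero")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # minor-allele copies (either allele works; symmetric)
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return 1.0

    # P(het = h | allele counts) ~ C(n, (n_a-h)/2, h, rest) * 2^h; enumerate
    # h with the parity of n_a, 0 <= h <= n_a
    hs = np.arange(n_a % 2, n_a + 1, 2)
    n_hom_min = (n_a - hs) // 2
    n_hom_maj = n - hs - n_hom_min
    logp = (hs * np.log(2.0) - gammaln(n_hom_min + 1) - gammaln(hs + 1)
            - gammaln(n_hom_maj + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    h_obs = n_Aa
    p_obs = probs[hs == h_obs][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_exact_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Per-variant HWE exact P over the non-missing genotype counts."""
    d = g.dosages
    n_aa = np.nansum(d == 2, axis=0).astype(int)
    n_het = np.nansum(d == 1, axis=0).astype(int)
    n_AA = np.nansum(d == 0, axis=0).astype(int)
    out = np.ones(g.n_variants)
    for j in range(g.n_variants):
        if n_AA[j] + n_het[j] + n_aa[j] > 0:
            out[j] = hwe_exact_test(n_AA[j], n_het[j], n_aa[j])
    return out


def variant_qc(g: GenotypeMatrix, t: QCThresholds) -> tuple[GenotypeMatrix, QCReport]:
    """Remove X/Y variants and those failing call-rate, MAF, or HWE filters."""
    if g.n_variants == 0 or g.n_samples == 0:
        raise ConfigurationError("empty genotype matrix")
    report = QCReport(n_variants_before=g.n_variants, n_samples_before=g.n_samples,
                      n_samples_after=g.n_samples)

    keep = np.ones(g.n_variants, dtype=bool)
    ids = g.variants["id"].to_numpy()

    sex_chrom = g.variants["chrom"].astype(str).str.upper().isin(
        ["X", "Y", "23", "24", "CHRX", "CHRY"]).to_numpy()
    _drop(report.removed_variants, ids, keep, sex_chrom, "sex_chromosome")

    call = g.call_rate()
    _drop(report.removed_variants, ids, keep, keep & (call < t.call_rate_min),
          "call_rate")

    freq = g.alt_allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    _drop(report.removed_variants, ids, keep, keep & (maf < t.maf_min), "maf")

    hwe_idx = np.where(keep)[0]
    hwe_p = hwe_exact_pvalues(g.subset(variant_idx=hwe_idx))
    fail = np.zeros(g.n_variants, dtype=bool)
    fail[hwe_idx[hwe_p < t.hwe_p_min]] = True
    _drop(report.removed_variants, ids, keep, fail, "hwe")

    if not keep.any():
        raise ConfigurationError("no variants survive QC")
    out = g.subset(variant_idx=np.where(keep)[0])
    report.n_variants_after = out.n_variants
    report.notes.append("variant filter order: sex_chromosome, call_rate, maf, hwe")
    return out, report


def _drop(removed: list, ids: np.ndarray, keep: np.ndarray,
          mask: np.ndarray, reason: str) -> None:
    for i in np.where(mask & keep)[0]:
        removed.append((str(ids[i]), reason))
    keep &= ~mask


def sample_qc(g: GenotypeMatrix, t: QCThresholds) -> tuple[GenotypeMatrix, QCReport]:
    """Remove samples with high missingness or outlying heterozygosity."""
    if g.n_samples < 3:
        raise ConfigurationError("sample QC needs at least 3 samples")
    report = QCReport(n_variants_before=g.n_variants, n_variants_after=g.n_variants,
                      n_samples_before=g.n_samples)
    ids = np.asarray(g.sample_ids)
    keep = np.ones(g.n_samples, dtype=bool)

    missing = np.mean(np.isnan(g.dosages), axis=1)
    _drop(report.removed_samples, ids, keep, missing > t.sample_missing_max,
          "missingness")

    nonmiss = ~np.isnan(g.dosages)
    with np.errstate(invalid="ignore"):
        het = np.nansum(g.dosages == 1, axis=1) / np.maximum(nonmiss.sum(axis=1), 1)
    mu, sd = het.mean(), het.std(ddof=1)
    if sd > 0:  # zero spread: no outliers by definition
        _drop(report.removed_samples, ids, keep,
              np.abs(het - mu) > t.het_sd * sd, "heterozygosity")

    if not keep.any():
        raise ConfigurationError("no samples survive QC")
    out = g.subset(sample_idx=np.where(keep)[0])
    report.n_samples_after = out.n_samples
    return out, report


def ld_prune(g: GenotypeMatrix, r2_max: float = 0.2, window: int = 100) -> np.ndarray:
    """Greedy LD pruning: indices of variants kept at pairwise r^2 < r2_max
    within a sliding window of ``window`` variants (per chromosome)."""
    d = g.imputed_dosages()
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    keep: list[int] = []
    chroms = g.variants["chrom"].to_numpy()
    for j in range(g.n_variants):
        if sd[j] == 0:
            continue
        ok = True
        for k in reversed(keep):
            if j - k > window or chroms[k] != chroms[j]:
                break
            r = float(d[:, j] @ d[:, k]) / (g.n_samples * sd[j] * sd[k])
            if r * r >= r2_max:
                ok = False
                break
        if ok:
            keep.append(j)
    return np.array(keep, dtype=int)


def estimate_relatedness(g: GenotypeMatrix) -> list[tuple[str, str, float]]:
    """Method-of-moments IBD estimation (PI_HAT) for every sample pair.

    For each pair, observed identity-by-state counts are combined with their
    allele-frequency expectations under IBD states 0/1/2 to give Z0, Z1, Z2;
    ``pi_hat = Z2 + Z1/2`` clamped to [0, 1]. Expects an LD-pruned panel.
    """
    if g.n_samples < 2:
        raise ConfigurationError("relatedness needs at least 2 samples")
    freq = g.alt_allele_freq()
    informative = np.isfinite(freq) & (freq > 0) & (freq < 1)
    if informative.sum() < 50:
        warnings.warn("fewer than 50 informative variants: PI_HAT estimates "
                      "are low-confidence", stacklevel=2)
    gg = g.subset(variant_idx=np.where(informative)[0])
    p = gg.alt_allele_freq()
    q = 1.0 - p
    d = gg.dosages

    # indicator matrices per genotype class, missing excluded everywhere
    A0 = (d == 0).astype(np.float64)
    A1 = (d == 1).astype(np.float64)
    A2 = (d == 2).astype(np.float64)
    M = (~np.isnan(d)).astype(np.float64)

    ibs0 = A0 @ A2.T + A2 @ A0.T
    ibs2 = A0 @ A0.T + A1 @ A1.T + A2 @ A2.T
    n_obs = M @ M.T
    ibs1 = n_obs - ibs0 - ibs2

    # per-variant IBS probabilities given IBD state
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibs1 = 2 * p**2 * q + 2 * p * q**2
    e1_ibs2 = p**3 + q**3 + p**2 * q + p * q**2

    def pair_expect(e: np.ndarray) -> np.ndarray:
        Me = M * e
        return Me @ M.T  # sum over variants observed in both samples

    E0_0, E0_1, E0_2 = pair_expect(e0_ibs0), pair_expect(e0_ibs1), pair_expect(e0_ibs2)
    E1_1, E1_2 = pair_expect(e1_ibs1), pair_expect(e1_ibs2)

    with np.errstate(divide="ignore", invalid="ignore"):
        Z0 = ibs0 / E0_0
        Z1 = (ibs1 - Z0 * E0_1) / E1_1
        Z2 = (ibs2 - Z0 * E0_2 - Z1 * E1_2) / n_obs
    pi_hat = np.clip(Z2 + 0.5 * Z1, 0.0, 1.0)

    out = []
    ids = gg.sample_ids
    for i in range(gg.n_samples):
        for j in range(i + 1, gg.n_samples):
            out.append((ids[i], ids[j], float(pi_hat[i, j])))
    return out


def related_exclusions(
    g: GenotypeMatrix,
    pairs: list[tuple[str, str, float]],
    relatedness_max: float = 0.125,
) -> list[str]:
    """Sample ids to drop so no retained pair exceeds ``relatedness_max``.

    Within each flagged pair the member with higher genotype missingness is
    removed (ties broken by lexicographic id).
    """
    missing = dict(zip(g.sample_ids, np.mean(np.isnan(g.dosages), axis=1)))
    dropped: set[str] = set()
    for a, b, pi in sorted(pairs, key=lambda t: -t[2]):
        if pi <= relatedness_max or a in dropped or b in dropped:
            continue
        worse = max(a, b, key=lambda s: (missing[s], s))
        dropped.add(worse)
    return sorted(dropped)


def compute_pcs(g: GenotypeMatrix, n_pcs: int = 3) -> AncestryPCs:
    """Ancestry principal components of the standardized genotype matrix.

    Missing dosages are mean-imputed; each variant is centered and scaled by
    ``sqrt(2 p (1-p))`` (unit variance under HWE); sample coordinates are the
    top left singular directions scaled by their singular values.
    Zero-variance variants are excluded with a warning.
    """
    if not n_pcs < min(g.n_samples, g.n_variants):
        raise ConfigurationError("n_pcs must be < min(n_samples, n_variants)")
    d = g.imputed_dosages()
    p = d.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    usable = denom > 0
    if not usable.all():
        warnings.warn(f"excluding {int((~usable).sum())} zero-variance variants "
                      "from PCA", stacklevel=2)
    x = (d[:, usable] - 2.0 * p[usable]) / denom[usable]

    # n_samples << n_variants: eigendecompose the (n x n) Gram matrix
    gram = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1][:n_pcs]
    evals = np.maximum(evals[order], 0.0)
    coords = evecs[:, order] * np.sqrt(np.maximum(evals, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        comps = (evecs[:, order].T @ x) / np.sqrt(
            np.maximum(evals[:, None], 1e-300) * x.shape[1])
    return AncestryPCs(sample_ids=list(g.sample_ids), coords=coords,
                       eigenvalues=evals, components=comps)


def run_qc(
    g: GenotypeMatrix, t: QCThresholds | None = None,
    prune_r2: float = 0.2, prune_window: int = 100,
) -> tuple[GenotypeMatrix, AncestryPCs, QCReport]:
    """Full QC chain: variant filters, sample filters, relatedness, PCA."""
    t = t or QCThresholds()
    g1, rep_v = variant_qc(g, t)
    g2, rep_s = sample_qc(g1, t)

    pruned = ld_prune(g2, r2_max=prune_r2, window=prune_window)
    pairs = estimate_relatedness(g2.subset(variant_idx=pruned))
    drop = related_exclusions(g2, pairs, t.relatedness_max)
    if drop:
        keep = [i for i, s in enumerate(g2.sample_ids) if s not in drop]
        g2 = g2.subset(sample_idx=keep)
    report = QCReport(
        removed_variants=rep_v.removed_variants,
        removed_samples=rep_s.removed_samples + [(s, "relatedness") for s in drop],
        n_variants_before=g.n_variants, n_variants_after=g2.n_variants,
        n_samples_before=g.n_samples, n_samples_after=g2.n_samples,
        notes=rep_v.notes + ["sample filter order: missingness, heterozygosity, "
                             "relatedness"],
    )
    pcs = compute_pcs(g2, t.n_pcs)
    return g2, pcs, report
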