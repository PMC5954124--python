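"""Core in-memory containers shared across the pipeline stages.

Genotypes live in a :class:`GenotypeMatrix` (samples x variants dosage matrix
with a variant metadata table); GWAS summary statistics, phenotype tables,
polygenic scores and association results are plain :class:`pandas.DataFrame`
objects with documented column schemas, validated by the helpers here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical order of the six ERP summary measures used throughout.
ERP_MEASURES = (
    "p50_ratio",      # P50 sensory gating ratio, (S2/S1) x 100, percent
    "s1_amplitude",   # amplitude of the S1 click response, uV
    "n1_amplitude",   # |N1| magnitude at Cz, uV (stored as a positive magnitude)
    "p2_amplitude",   # P2 amplitude at Cz, uV
    "p3_amplitude",   # P3 amplitude at Pz, uV
    "p3_latency",     # P3 latency at Pz, ms
)

#: Direction of worse function per measure (+1: higher is worse, -1: lower is
#: worse). P50 ratio and P3 latency increase with impairment; the response
#: amplitudes (S1, |N1|, P2, P3) shrink with impairment.
IMPAIRMENT_DIRECTIONS = np.array([+1.0, -1.0, -1.0, -1.0, -1.0, +1.0])

#: Required columns of a GWAS summary-statistics frame.
SUMSTAT_COLUMNS = ("chrom", "pos", "id", "effect_allele", "other_allele",
                   "effect", "se", "p")

_BASES = ("A", "C", "G", "T")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class ConfigurationError(ValueError):
    """Raised when a configuration object or input violates a precondition."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    Parameters
    ----------
    sample_ids
        Sequence of unique sample identifiers, length ``n_samples``.
    variants
        DataFrame with columns ``chrom`` (str), ``pos`` (1-based int), ``id``
        (unique str), ``ref``, ``alt`` (single-character bases); one row per
        variant, positions strictly increasing within a chromosome.
    dosages
        ``(n_samples, n_variants)`` float array of alt-allele counts in
        {0, 1, 2}; missing genotypes are NaN.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ConfigurationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        """Check the container invariants; raise ``ConfigurationError`` if violated."""
        if len(set(self.sample_ids)) != self.n_samples:
            raise ConfigurationError("duplicate sample ids")
        v = self.variants
        if v["id"].duplicated().any():
            raise ConfigurationError("duplicate variant ids")
        for _, sub in v.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ConfigurationError("positions not strictly increasing within chromosome")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            raise ConfigurationError("dosages must be in {0, 1, 2} or missing")

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given positional indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            variants=self.variants.iloc[vi].reset_index(drop=True),
            dosages=self.dosages[np.ix_(si, vi)],
        )

    def alt_allele_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency from non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the variant mean (float64)."""
        d = self.dosages.astype(np.float64)
        mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        idx = np.where(np.isnan(d))
        d[idx] = mean[idx[1]]
        return d


def is_strand_ambiguous(a1, a2) -> bool:
    """True for A/T and C/G pairs, which cannot be resolved across strands."""
    return (str(a1).upper(), str(a2).upper()) in _AMBIGUOUS_PAIRS


def validate_sumstats(ss: pd.DataFrame) -> pd.DataFrame:
    """Validate a summary-statistics frame against the schema; returns it."""
    missing = [c for c in SUMSTAT_COLUMNS if c not in ss.columns]
    if missing:
        raise ConfigurationError(f"summary statistics missing columns: {missing}")
    if ss["id"].duplicated().any():
        raise ConfigurationError("duplicate variant ids in summary statistics")
    p = ss["p"].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ConfigurationError("p-values must lie in (0, 1]")
    if np.any(ss["se"].to_numpy(dtype=float) <= 0):
        raise ConfigurationError("standard errors must be positive")
    if np.any(~np.isfinite(ss["effect"].to_numpy(dtype=float))):
        raise ConfigurationError("effects must be finite")
    return ss


@dataclass
class AncestryPCs:
    """Top principal components of the standardized genotype matrix.

    ``coords`` is ``(n_samples, n_pcs)``; ``eigenvalues`` are the matching
    non-increasing eigenvalues of the sample covariance; ``components`` the
    orthonormal variant-space loadings (``n_pcs x n_used_variants``).
    """

    sample_ids: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.coords[:, i] for i in range(self.coords.shape[1])}
        return pd.DataFrame(cols, index=pd.Index(self.sample_ids, name="sample_id"))
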