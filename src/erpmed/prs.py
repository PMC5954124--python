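"""Polygenic risk scoring: allele harmonization, LD clumping, and
multi-threshold weighted allele sums.

Clumping is the greedy clump-and-threshold procedure: visit variants in
ascending discovery P-value, retain each not-yet-removed variant as an index
SNP and remove its LD partners (target-sample r^2 above ``r2_max``) within
``window_kb`` of its position. The extended MHC region (chr6:26-33 Mb) is
excluded before clumping. Scores at each P-value threshold are
Sum_j dosage_ij * effect_j over the index SNPs with p <= threshold, with
missing dosages imputed as twice the target-sample effect-allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ConfigurationError,
    GenotypeMatrix,
    is_strand_ambiguous,
    validate_sumstats,
)

DEFAULT_THRESHOLDS = (0.001, 0.01, 0.05, 0.1, 0.5)


@dataclass
class ClumpConfig:
    """Clumping and scoring parameters."""

    window_kb: float = 250.0
    r2_max: float = 0.1
    mhc_chrom: str = "6"
    mhc_start: int = 26_000_000  # 1-based inclusive
    mhc_end: int = 33_000_000
    exclude_mhc: bool = True
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if self.window_kb <= 0:
            raise ConfigurationError("window_kb must be positive")
        if not (0 < self.r2_max < 1):
            raise ConfigurationError("r2_max must lie in (0, 1)")
        if any(not (0 < t <= 1) for t in self.thresholds):
            raise ConfigurationError("thresholds must lie in (0, 1]")
        self.thresholds = tuple(sorted(self.thresholds))


def harmonize_alleles(
    sumstats: pd.DataFrame, g: GenotypeMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align discovery effects to the target genotype orientation.

    Variants are matched by chromosome and position. When the discovery
    effect allele is the target's *ref* allele (alleles swapped), the effect
    sign is flipped so every retained effect counts target alt-allele copies.
    Strand-ambiguous (A/T, C/G) and allele-mismatched variants are dropped.

    Returns the harmonized summary statistics (with a ``variant_index``
    column into ``g``) and a drop report (id, reason).
    """
    validate_sumstats(sumstats)
    target = g.variants.reset_index().rename(columns={"index": "variant_index"})
    merged = sumstats.merge(
        target[["variant_index", "chrom", "pos", "ref", "alt"]],
        on=["chrom", "pos"], how="inner")

    drops: list[tuple[str, str]] = []
    unmatched = set(sumstats["id"]) - set(merged["id"])
    drops += [(v, "unmatched") for v in sorted(unmatched)]

    keep_rows = []
    for row in merged.itertuples(index=False):
        ea, oa = str(row.effect_allele), str(row.other_allele)
        if is_strand_ambiguous(ea, oa):
            drops.append((row.id, "ambiguous"))
            continue
        if {ea, oa} != {str(row.ref), str(row.alt)}:
            drops.append((row.id, "allele_mismatch"))
            continue
        keep_rows.append(row)
    if not keep_rows:
        raise ConfigurationError("no variants overlap between summary "
                                 "statistics and target genotypes")

    out = pd.DataFrame(keep_rows)
    flip = out["effect_allele"] == out["ref"]
    out.loc[flip, "effect"] = -out.loc[flip, "effect"]
    out.loc[flip, ["effect_allele", "other_allele"]] = (
        out.loc[flip, ["other_allele", "effect_allele"]].to_numpy())
    out = out.drop(columns=["ref", "alt"]).reset_index(drop=True)
    report = pd.DataFrame(drops, columns=["id", "reason"])
    return out, report


def ld_clump(
    sumstats: pd.DataFrame, g: GenotypeMatrix, cfg: ClumpConfig | None = None
) -> pd.DataFrame:
    """Greedy LD clumping against the target-sample LD.

    Requires harmonized input (a ``variant_index`` column from
    :func:`harmonize_alleles`). P-value ties are broken by (chromosome,
    position) ascending so the result is deterministic. Returns the retained
    index SNPs in their original row order.
    """
    cfg = cfg or ClumpConfig()
    if "variant_index" not in sumstats.columns:
        raise ConfigurationError("ld_clump requires harmonized summary statistics")
    ss = sumstats.reset_index(drop=True)
    if ss["pos"].isna().any():
        raise ConfigurationError("missing positions")

    if cfg.exclude_mhc:
        in_mhc = ((ss["chrom"].astype(str) == cfg.mhc_chrom)
                  & (ss["pos"] >= cfg.mhc_start) & (ss["pos"] <= cfg.mhc_end))
        ss = ss[~in_mhc].reset_index(drop=True)
        if ss.empty:
            raise ConfigurationError("all variants fall in the excluded MHC region")

    # centered, mean-imputed dosages for r^2 in the target sample
    d = g.imputed_dosages()[:, ss["variant_index"].to_numpy()]
    d = d - d.mean(axis=0)
    norms = np.sqrt((d ** 2).sum(axis=0))

    chroms = ss["chrom"].to_numpy()
    pos = ss["pos"].to_numpy()
    window = cfg.window_kb * 1000.0

    order = np.lexsort((pos, chroms, ss["p"].to_numpy()))
    removed = np.zeros(len(ss), dtype=bool)
    retained = np.zeros(len(ss), dtype=bool)
    # per-chromosome position-sorted index for window lookups
    by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(chroms):
        idx = np.where(chroms == c)[0]
        by_chrom[c] = idx[np.argsort(pos[idx])]

    for i in order:
        if removed[i]:
            continue
        retained[i] = True
        cand = by_chrom[chroms[i]]
        lo = np.searchsorted(pos[cand], pos[i] - window, side="left")
        hi = np.searchsorted(pos[cand], pos[i] + window, side="right")
        near = cand[lo:hi]
        near = near[(near != i) & ~retained[near] & ~removed[near]]
        if near.size == 0 or norms[i] == 0:
            continue
        ok = norms[near] > 0
        r = np.zeros(near.size)
        r[ok] = (d[:, near[ok]].T @ d[:, i]) / (norms[near[ok]] * norms[i])
        removed[near[r * r > cfg.r2_max]] = True

    return ss[retained].reset_index(drop=True)


def compute_prs(
    g: GenotypeMatrix,
    clumped: pd.DataFrame,
    cfg: ClumpConfig | None = None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Weighted allele-sum scores at each P-value threshold.

    Returns a long-format frame (sample_id, trait, p_threshold, score,
    n_snps). A threshold selecting no index SNPs yields score 0 with
    ``n_snps = 0``.
    """
    cfg = cfg or ClumpConfig()
    if "variant_index" not in clumped.columns:
        raise ConfigurationError("compute_prs requires harmonized, clumped input")
    vidx = clumped["variant_index"].to_numpy()
    d = g.dosages[:, vidx].astype(np.float64)
    freq = np.nanmean(d, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    fill = np.broadcast_to(2.0 * freq, d.shape)
    d = np.where(np.isnan(d), fill, d)

    records = []
    p = clumped["p"].to_numpy()
    eff = clumped["effect"].to_numpy()
    for pt in cfg.thresholds:
        sel = p <= pt
        score = d[:, sel] @ eff[sel] if sel.any() else np.zeros(g.n_samples)
        for sid, s in zip(g.sample_ids, score):
            records.append((sid, trait, pt, float(s), int(sel.sum())))
    return pd.DataFrame(records, columns=["sample_id", "trait", "p_threshold",
                                          "score", "n_snps"])


def score_pipeline(
    g: GenotypeMatrix,
    sumstats_by_trait: dict[str, pd.DataFrame],
    cfg: ClumpConfig | None = None,
) -> pd.DataFrame:
    """Harmonize, clump, and score every trait; concatenated long frame."""
    cfg = cfg or ClumpConfig()
    frames = []
    for trait, ss in sumstats_by_trait.items():
        harm, _ = harmonize_alleles(ss, g)
        clumped = ld_clump(harm, g, cfg)
        frames.append(compute_prs(g, clumped, cfg, trait=trait))
    return pd.concat(frames, ignore_index=True)
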