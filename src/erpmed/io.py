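"""Readers and writers for the standard file formats.

Genotypes: VCF (unphased GT; read via cyvcf2), PLINK-1 binary triplet
(.bed/.bim/.fam), or a plain dosage TSV (variants as columns). Summary
statistics, phenotypes, PCs, scores and reports are tab-separated text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConfigurationError, GenotypeMatrix, validate_sumstats

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


# ---------------------------------------------------------------------------
# VCF

def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write unphased GT records, one ALT allele per site."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(g.variants["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        d = g.dosages
        for j, row in enumerate(g.variants.itertuples(index=False)):
            gts = "\t".join(
                "./." if np.isnan(d[i, j]) else _GT_STRINGS[float(d[i, j])]
                for i in range(g.n_samples))
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic GT records into a dosage matrix (alt-allele counts)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        rows.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}",
                     var.REF, var.ALT[0]))
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        dosage_cols.append(col)
    if not rows:
        raise ConfigurationError(f"no biallelic variants in {path}")
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeMatrix(sample_ids=samples, variants=variants,
                          dosages=np.column_stack(dosage_cols))


# ---------------------------------------------------------------------------
# PLINK-1 binary

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major

def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write a .bed/.bim/.fam triplet (SNP-major, A1 = alt allele)."""
    prefix = Path(prefix)
    bim = pd.DataFrame({
        "chrom": g.variants["chrom"], "id": g.variants["id"], "cm": 0,
        "pos": g.variants["pos"], "a1": g.variants["alt"], "a2": g.variants["ref"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": g.sample_ids, "iid": g.sample_ids, "pat": 0, "mat": 0,
        "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    # two bits per sample per variant: 00=hom A1(alt=2), 01=missing,
    # 10=het, 11=hom A2(ref=0)
    code = np.full(g.dosages.shape, 0b01, dtype=np.uint8)  # missing
    code[g.dosages == 2] = 0b00
    code[g.dosages == 1] = 0b10
    code[g.dosages == 0] = 0b11
    n = g.n_samples
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        padded = np.zeros((n_bytes * 4, g.n_variants), dtype=np.uint8)
        padded[:n] = code
        packed = np.zeros((n_bytes, g.n_variants), dtype=np.uint8)
        for k in range(4):
            packed |= (padded[k::4] << (2 * k)).astype(np.uint8)
        fh.write(packed.T.tobytes())


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK-1 .bed/.bim/.fam triplet (SNP-major)."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ConfigurationError(f"{prefix}.bed is not a SNP-major PLINK-1 file")
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    # unpack 2-bit codes, sample-fastest within byte
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    codes = codes[:, :n]
    dosage = np.select([codes == 0b00, codes == 0b10, codes == 0b11],
                       [2.0, 1.0, 0.0], np.nan)
    variants = pd.DataFrame({
        "chrom": bim["chrom"].astype(str), "pos": bim["pos"], "id": bim["id"],
        "ref": bim["a2"], "alt": bim["a1"],
    })
    return GenotypeMatrix(sample_ids=list(fam["iid"].astype(str)),
                          variants=variants, dosages=dosage.T)


# ---------------------------------------------------------------------------
# dosage / tabular formats

def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    """Dosage TSV: variant metadata columns then one column per sample."""
    meta = g.variants.copy()
    dose = pd.DataFrame(g.dosages.T, columns=g.sample_ids)
    pd.concat([meta.reset_index(drop=True), dose], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    meta_cols = ["chrom", "pos", "id", "ref", "alt"]
    if not set(meta_cols).issubset(df.columns):
        raise ConfigurationError(f"dosage table must carry columns {meta_cols}")
    samples = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(sample_ids=samples, variants=df[meta_cols].copy(),
                          dosages=df[samples].to_numpy(dtype=float).T)


def write_sumstats(ss: pd.DataFrame, path) -> None:
    out = ss.rename(columns={"chrom": "CHR", "pos": "POS", "id": "SNP",
                             "effect_allele": "A1", "other_allele": "A2",
                             "effect": "EFFECT", "se": "SE", "p": "P"})
    out[["CHR", "POS", "SNP", "A1", "A2", "EFFECT", "SE", "P"]].to_csv(
        path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    df = df.rename(columns={"CHR": "chrom", "POS": "pos", "SNP": "id",
                            "A1": "effect_allele", "A2": "other_allele",
                            "EFFECT": "effect", "SE": "se", "P": "p"})
    return validate_sumstats(df)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
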