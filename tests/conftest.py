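import numpy as np
import pandas as pd
import pytest

from erpmed import SimulationConfig, simulate_cohort
from erpmed.containers import GenotypeMatrix


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_variants=2000, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One modest synthetic cohort shared across read-only tests."""
    return simulate_cohort(small_config)


def make_genotypes(dosages, chrom="1", start=1_000_000, spacing=10_000,
                   ref="A", alt="G"):
    """Hand-built GenotypeMatrix from a dosage array (rows = samples)."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    if np.isscalar(chrom) or isinstance(chrom, str):
        chrom = [chrom] * m
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": start + spacing * np.arange(m),
        "id": [f"v{j}" for j in range(m)],
        "ref": [ref] * m if isinstance(ref, str) else ref,
        "alt": [alt] * m if isinstance(alt, str) else alt,
    })
    return GenotypeMatrix([f"S{i}" for i in range(n)], variants, d)


@pytest.fixture
def make_geno():
    return make_genotypes
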