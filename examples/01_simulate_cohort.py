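"""Generate a synthetic psychosis cohort and inspect its structure.

Builds the default cohort (383 samples: ~136 SCZ, ~122 BPD, ~125 controls),
with LD-blocked genotypes, four discovery GWAS summary-statistic sets, and
the six-measure ERP phenotype table with its latent three-cluster structure.
"""

import numpy as np

from erpmed import SimulationConfig, simulate_cohort

config = SimulationConfig(n_variants=10_000, seed=1)
genotypes, sumstats, phenotypes = simulate_cohort(config)

print(f"genotypes: {genotypes.n_samples} samples x {genotypes.n_variants} variants")
print(f"mean alt-allele frequency: {np.nanmean(genotypes.alt_allele_freq()):.3f}")
print(f"discovery traits: {sorted(sumstats)}")

print("\ndiagnosis mix:", phenotypes["diagnosis"].value_counts().to_dict())
print("latent cluster sizes (0 = globally impaired):",
      phenotypes["true_cluster"].value_counts().sort_index().to_dict())
print("cases with a PANSS-positive score:",
      int(phenotypes["panss_positive"].notna().sum()))

# The impaired cluster should look worse on every ERP measure, e.g. higher
# P50 ratio (poorer sensory gating) and smaller P3 amplitude.
for measure in ("p50_ratio", "p3_amplitude"):
    by = phenotypes.groupby("true_cluster")[measure].mean()
    print(f"{measure} by cluster:", {k: round(v, 1) for k, v in by.items()})
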