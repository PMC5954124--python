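"""Genotype QC, ancestry PCs, and ERP clustering.

Runs the array-QC chain (variant filters, sample filters, relatedness,
PCA), then derives the ERP clusters: V-fold cross-validation picks the
number of clusters, K-means fits it, and the cluster that is worst on all
six measures is labeled "globally impaired".
"""

from erpmed import SimulationConfig, simulate_cohort
from erpmed.cluster import fit_kmeans, label_globally_impaired, select_k_vfold
from erpmed.containers import ERP_MEASURES
from erpmed.qc import QCThresholds, run_qc

config = SimulationConfig(n_variants=10_000, seed=2)
genotypes, _, phenotypes = simulate_cohort(config)

g_clean, pcs, report = run_qc(genotypes, QCThresholds())
print(f"QC: {report.n_samples_before} -> {report.n_samples_after} samples, "
      f"{report.n_variants_before} -> {report.n_variants_after} variants")
print(f"removed variants by reason: "
      f"{ {r: sum(1 for _, x in report.removed_variants if x == r) for r in {x for _, x in report.removed_variants} } }")
print("top-3 eigenvalues:", [round(float(v), 3) for v in pcs.eigenvalues])

profiles = phenotypes.loc[g_clean.sample_ids, list(ERP_MEASURES)]
selection = select_k_vfold(profiles, (2, 3, 4, 5), v=10, seed=2)
print("\nheld-out error by k:",
      {k: round(v, 3) for k, v in selection.heldout_error.items()})
print("chosen k:", selection.chosen_k)

model = label_globally_impaired(fit_kmeans(profiles, selection.chosen_k, seed=2))
n_gi = int(model.gi_indicator().sum())
print(f"globally impaired cluster: {n_gi} of {len(profiles)} subjects")
print("direction-aligned centroid of the GI cluster (z-units, higher = worse):",
      [round(float(v), 2) for v in
       model.centroids[model.gi_cluster] * model.impairment_directions])
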