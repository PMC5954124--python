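# erpmed

Polygenic scores, ERP phenotype clustering, and counterfactual mediation
analysis for psychosis cohorts.

## The problem

Event-related potentials (ERPs) — stereotyped EEG responses such as P50
sensory gating, N1/P2, and P3 — are heritable neurophysiological markers that
are broadly impaired in a subset of people with psychotic illness. Clustering
patients and controls on a panel of ERP summary measures yields a "globally
impaired" subgroup: people who are abnormal on *every* measure. `erpmed`
implements the full inference chain that connects common genetic variation to
this phenotype and onward to psychotic symptom severity:

1. **Genotype QC and ancestry** — MAF / call-rate / Hardy–Weinberg exact-test
   variant filters, missingness and heterozygosity sample filters,
   method-of-moments relatedness (PI_HAT) exclusion, and PCA of the
   standardized genotype matrix.
2. **ERP clustering** — K-means over six z-scored ERP measures (P50 ratio =
   (S2/S1)×100, S1 amplitude, |N1|, P2, P3 amplitude, P3 latency), with the
   number of clusters chosen by V-fold cross-validation and the worst-on-all-
   measures cluster labeled *globally impaired* (GI).
3. **Polygenic risk scores** — clump + threshold scoring from discovery GWAS
   summary statistics: greedy LD clumping (±250 kb, r² > 0.1, MHC chr6:26–33 Mb
   excluded) and weighted allele sums `PRS_i = Σ_j dosage_ij · β̂_j` at
   P-value thresholds {0.001, 0.01, 0.05, 0.1, 0.5}.
4. **Association** — logistic models `GI ~ PRS + PC1..PC3`, Wald tests,
   incremental Nagelkerke R² (full minus covariates-only), and
   Benjamini–Hochberg q-values across the 20 trait×threshold tests.
5. **Counterfactual mediation** — for a binary exposure A (top vs bottom PRS
   quartile), binary mediator M (GI membership) and outcome Y (PANSS-positive
   score), the natural direct and indirect effects from the fitted models
   `logit P(M=1|A,C) = b0 + b1 A + b2'C` and
   `E[Y|A,M,C] = t0 + t1 A + t2 M + t3 AM + t4'C`:

   NDE = (t1 + t3·expit(b0 + b1 a* + b2'c))·(a − a*)
   NIE = (t2 + t3·a)·(expit(b0 + b1 a + b2'c) − expit(b0 + b1 a* + b2'c))

   with total = NDE + NIE, proportion mediated = NIE/total, 95% bias-corrected
   bootstrap intervals (200 replicates), rare-outcome odds-ratio analogues for
   binary outcomes, and a simulated-confounder sensitivity analysis for
   unmeasured mediator–outcome confounding.

Because cohort data of this kind are not publicly distributable, the package
ships a first-class **synthetic cohort generator** that reproduces the
statistical structure every stage assumes — LD-blocked genotypes, noisy
discovery GWAS, a latent three-cluster ERP mixture whose impaired cluster
loads on a true polygenic score, and a configurable
PRS → GI → PANSS mediation structure — so the entire chain is testable end to
end with known ground truth.

## Worked example

```bash
python examples/02_qc_and_cluster.py
```

prints (abridged):

```
QC: 383 -> 383 samples, 10000 -> 9915 variants
held-out error by k: {2: 2.956, 3: 1.787, 4: 1.675, 5: 1.621}
chosen k: 3
globally impaired cluster: 62 of 383 subjects
direction-aligned centroid of the GI cluster (z-units, higher = worse):
  [1.49, 1.43, 1.43, 1.41, 1.53, 1.61]
```

The V-fold error drops sharply from k=2 to k=3 and only marginally beyond, so
3 clusters are selected; the GI cluster (~60 of 383 subjects, matching the
generating mixture) sits 1.4–1.6 SD toward impairment on *all six* measures —
that is what "globally impaired" means operationally. The other examples
cover cohort simulation (`01`), PRS association (`03`, where the
college-completion score dominates by construction of the generator), and
mediation with sensitivity analysis (`04`).

The same stages are available from the shell:

```bash
erpmed run --synthetic --seed 1 --out-dir out/
erpmed simulate --out-dir data/ --seed 1
erpmed score --geno data/genotypes.bed --sumstats data/sumstats_college.tsv \
             --trait college --out scores.tsv
```

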