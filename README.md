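# admixscan

Admixture inference and ancestry-enrichment scanning for multi-source
genotype cohorts.

Admixed populations — such as Latin American cohorts carrying three-way
African, Indigenous American and European ancestry — show large allele
frequency differences between ancestry groups at clinically relevant
variants. `admixscan` provides a tested, reproducible pipeline for the
analyses such a cohort needs:

- **Harmonization**: read per-dataset VCFs, canonicalize variant identities
  to the gnomAD `chrom:pos:ref:alt` convention, fix or drop allele-swapped
  records, union-merge datasets on canonical id, and apply standard QC —
  sample missingness, duplicate/first-degree-relative removal via the
  KING-robust kinship estimator, site missingness and MAF filters, LD
  pruning, seeded site subsampling.
- **Ancestry inference**: reference-panel PCA with projection of cohort
  samples, a K=3 admixture model fitted by EM on the binomial likelihood

  `L(Q, F) = Σ_ij [ g_ij log(Σ_k q_ik f_kj) + (2 − g_ij) log(1 − Σ_k q_ik f_kj) ]`

  (supervised or unsupervised, with reference-panel component alignment),
  and K-means clustering of the ancestry fractions with elbow selection of
  the cluster count.
- **Enrichment scan**: per-variant 2×C Fisher exact test on cluster allele
  counts (full enumeration, a deterministic tail bound, or Monte-Carlo
  sampling of margin-fixed tables, chosen automatically), multi-group
  fixation index `F_ST = 1 − H̄_S / H_T`, and Poisson regressions
  `genotype ~ ancestry` for significant variants.
- **Annotation**: joins against local ClinVar-like and PharmGKB-like
  snapshots, high-evidence filtering (levels 1A/1B/2A/2B), and per-group
  diagnostic yield `D_ip = 100 · #annotated / #observed variants`.
- **Ancestry-specific allele frequencies**: the per-ancestry frequency MLE
  from admixed genotypes plus ancestry fractions, projected to region-level
  frequencies through ancestry-composition weights.
- **Synthetic cohorts**: a generator producing admixed cohorts with known
  truth (Balding–Nichols drifted ancestral frequencies, Dirichlet ancestry
  vectors around five cluster archetypes, planted ancestry-enriched
  variants, sparse annotations) so every stage is testable without access
  to controlled genotype data.

The inference components are scikit-learn-style estimators
(`ReferencePCA`, `AdmixtureEM`, `ElbowKMeans`, `AncestrySpecificAF`) and
compose with sklearn tooling; module-level functions wrap them.

## Worked example

```python
import numpy as np
from admixscan import (
    CohortSpec, simulate_cohort, AdmixtureEM, ElbowKMeans,
    name_clusters, genome_scan,
)

cohort = simulate_cohort(CohortSpec(n_samples=300, n_variants=1000,
                                    n_planted=5, seed=1))
est = AdmixtureEM(mode="supervised", random_state=1).fit(
    cohort.matrix, reference_freqs=cohort.freqs.freqs)
print("mean ancestry (%):", np.round(100 * est.Q_.mean(axis=0), 1))

km = ElbowKMeans(random_state=1).fit(est.Q_)
names = name_clusters(km.cluster_means_)
print("clusters:", km.n_clusters_, sorted(names))

labels = np.array([names[l] for l in km.labels_], dtype=object)
scan = genome_scan(cohort.matrix, labels, est.Q_, mc_reps=2000, seed=2)
top = scan.iloc[0]
print("top hit:", top.variant_id, "p=%.2e" % top.fisher_p,
      "fst=%.3f" % top.fst, top.enriched_cluster)
```

Output:

```
mean ancestry (%): [15.9 36.5 47.6]
clusters: 5 ['ADX1', 'ADX2', 'AFR-like', 'AME-like', 'EUR-like']
top hit: 3:54000:A:G p=1.36e-40 fst=0.317 AME-like
```

The generator's design means are 16.7% African, 32.8% American and 50.6%
European ancestry (a 300-sample draw scatters a few points around them);
the elbow rule recovers the five planted ancestry clusters (three
near-pure, two admixed); the top scan hit is one of the planted
American-enriched variants, with an exact-test p-value far below the
genome-wide threshold of 5e-8 and an elevated fixation index.

The same stages run from the shell against a TOML config:

```sh
admixscan run-all --config run.toml --seed 1 --out results/
admixscan report --out results/
```

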