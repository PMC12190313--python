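# Methods

## The generative admixture model

All inference in `admixscan` is organised around one generative model.
K ancestral source populations (African, Indigenous American, European;
K = 3 throughout, the labels ordered AFR/AME/EUR) carry alternate-allele
frequencies `f_kj ∈ [0,1]` at each biallelic autosomal variant j.  Each
sample i owns a simplex vector `q_i` of ancestry fractions, and its
unphased diploid genotype is

    g_ij ~ Binomial(2, Σ_k q_ik f_kj),

i.e. each of the two allele copies descends from ancestry k with
probability `q_ik` and is then an alternate allele with probability
`f_kj`.  Variants are treated as independent (no linkage disequilibrium),
sex chromosomes, indels and multi-allelic sites are out of scope, and
missing genotypes are missing completely at random.

## Synthetic cohorts (`simdata`)

The generator draws from exactly this model so that the inference stages
can be tested against known truth:

- **Ancestral frequencies.**  A base frequency `p_j ~ Uniform(0.05, 0.95)`
  drifts independently in each population under the Balding–Nichols model,
  `f_kj ~ Beta(p_j (1−F_k)/F_k, (1−p_j)(1−F_k)/F_k)`, which has mean `p_j`
  and variance `F_k p_j (1−p_j)`.  Defaults `F = (0.15, 0.20, 0.10)` give
  continental-scale differentiation: the expected pairwise FST between two
  drifted populations is of the order of their F values, matching what
  African/American/European panels show.
- **Cluster structure.**  Five archetypes on the simplex — three near-pure
  `(0.90, 0.05, 0.05)`-style vertices and two admixed centres
  `(0.15, 0.15, 0.70)` and `(0.25, 0.45, 0.30)` — with sampling weights
  `(0.063, 0.207, 0.289, 0.250, 0.191)`.  The weights were solved once by
  constrained least squares so the cohort-mean ancestry is approximately
  16.7 % African, 32.8 % American and 50.6 % European, the composition
  reported for Colombian cohorts; all five clusters stay non-trivially
  occupied.  Within a cluster, `q_i ~ Dirichlet(c · archetype)` with
  concentration `c = 100`, giving a within-cluster spread (s.d. ≈ 0.03–0.05
  per component) well below the separation between archetypes.
- **Planted enriched variants** overwrite drawn frequency vectors with
  divergent ones (default cycle `(0.85, 0.15, 0.15)` and rotations,
  divergence 0.7) to provide positive controls with known enriched
  ancestry and effect sign.
- **Annotations.**  A configurable fraction (default 10 %) of variants gets
  one of three pathogenicity classes (uncertain 60 %, conflicting 30 %,
  pathogenic/likely pathogenic 10 % — rarest, as in clinical databases);
  planted variants get pharmacogenomic records with evidence levels drawn
  from {1A, 1B, 2A, 2B, 3, 4}.
- **Reproducibility.**  One integer seed drives a single
  `numpy.random.Generator`; fixed seed gives byte-identical VCFs and truth
  tables.

What the generator does **not** emulate: linkage disequilibrium (so LD
pruning is exercised only on planted duplicate columns and null
correlation), genotyping-platform batch effects, related samples (kinship
tests construct their own duplicates and trios), allele-frequency spectra
skewed toward rare variants, and informative missingness.  Passing tests
therefore demonstrate correctness of the estimators under the model's
assumptions, not robustness to real-data artefacts.

## Harmonization (`harmonize`)

Variant identity is `chrom:pos:ref:alt` (prefix-free chromosome dialect,
1-based positions, genome-build tag carried but never lifted over).
Allele-swap resolution against a truth dictionary keeps matching records,
flips exactly-swapped ones (`g → 2 − g`), and drops irreconcilable ones
with a logged reason code.  Union-merge joins datasets on canonical id;
entries absent from a source are missing; sample ids must be globally
unique (dataset prefixing).

Kinship uses the KING-robust between-family estimator
`φ̂ = (N_het,het − 2 N_opp-hom) / (N_het(i) + N_het(j))` over sites
non-missing in both samples; `φ̂ ≈ 0.5` for duplicates, `≈ 0.25` for
first-degree pairs.  The default removal threshold 0.177 (the conventional
first-degree cutoff, the geometric midpoint between 0.25 and 0.125)
removes both duplicates and first-degree relatives, dropping the
higher-missingness member (ties: later sample id).  Pairs sharing fewer
than 50 informative sites are skipped with a warning; a zero denominator
is guarded to φ̂ = 0.

Site filters remove variants with > 75 % missingness or < 5 % minor allele
frequency.  LD pruning slides a window (defaults 50 variants, step 5) per
chromosome and removes the lower-MAF member of any pair with squared
dosage correlation above 0.1, computed on mean-imputed dosages — composite
(unphased) LD, as in standard pruning practice.  The window/step/r²
defaults are conventional and config-exposed, since they are a tooling
choice rather than a property of the data.

## Ancestry inference (`ancestry`)

**PCA.**  Genotypes are standardized per site by mean `2p̂` and scale
`sqrt(2p̂(1−p̂))` with `p̂` the reference-panel frequency (monomorphic
sites dropped, residual missingness mean-imputed), and the panel is
decomposed by SVD.  Cohort samples are projected onto the panel's
eigenvectors; a projected cohort must share at least 50 % of model sites.
Percent variance per component is `eigenvalue / trace`.

**Admixture EM.**  The log-likelihood above is maximized by an
allele-allocation EM: the E-step attributes each observed alternate
(reference) allele copy to ancestry k with probability proportional to
`q_ik f_kj` (`q_ik (1 − f_kj)`); the M-step sets `q_ik` to the sample's
allocated copy share and, in unsupervised mode, `f_kj` to the allocated
alternate fraction.  Both updates use the same E-step, the complete-data
likelihood separates in Q and F, and the iteration is provably monotone in
the observed-data log-likelihood.  Numerical choices: F is clamped to
`[1e-6, 1 − 1e-6]` to keep the likelihood finite; Q rows are renormalized
each iteration (their sums are exactly 1 in exact arithmetic, and without
renormalization float drift compounds geometrically and eventually breaks
monotonicity); missing genotypes contribute to no sum.  Convergence is a
log-likelihood gain below `tol` (default 1e-4) with a 2,000-iteration cap;
hitting the cap sets a non-convergence flag rather than raising, since Q
stabilizes long before the likelihood tail flattens.  Unsupervised fits
start from `q ~ Dirichlet(1)` and site frequencies jittered ±0.05, with 3
seeded restarts keeping the best likelihood; supervised mode fixes F at
reference-panel frequencies and needs no restarts (the problem is concave
in each `q_i`).  Unsupervised components are aligned to reference
populations by Hungarian assignment on mean ancestry fractions; an
assignment in which a population's matched component is not its best
component is reported as ambiguous.

**Cluster count.**  K-means (k-means++/Lloyd, best of 10 restarts) is fit
for k = 1..10 and the cluster count is chosen at the sharpest bend of the
SSE curve.  The curvature is taken on **log SSE** by default: the raw
second difference `SSE(k−1) − 2·SSE(k) + SSE(k+1)` is dominated by the
first split whenever the leading eigendirection carries most of the
variance — on the five-archetype geometry it selects k = 2 even with zero
within-cluster spread — whereas the log rule rewards the k beyond which
SSE stops shrinking multiplicatively and recovers the planted count
reliably.  The raw rule remains available (`criterion="raw"`).  Clusters
whose mean ancestry vector has a component ≥ 0.75 are named
`<component>-like`; the rest are ADX1, ADX2, … by descending mean European
fraction.  The 0.75 threshold is a naming convention, config-exposed.

## Enrichment scan (`scan`)

Per variant, reference/alternate allele counts are tabulated per cluster
(missing genotypes contribute nothing; clusters with no calls drop their
column with a warning).  The **exact test** uses the probability-ordering
criterion: with margins fixed, p is the total conditional probability of
all tables no more probable than the observed one (a multiplicative
`1 + 1e-7` slack absorbs float ties, matching the classical convention).
Three evaluation routes, chosen automatically:

1. **Full enumeration** when the exact number of margin-fixed tables
   (computed by DP convolution) is at most `enum_max` — vectorized
   depth-first expansion with capacity pruning, chunked to bound memory.
2. **Deterministic tail bound** `p ≤ n_tables · Pr(observed)` when
   enumeration is infeasible but the bound already resolves below the
   Monte-Carlo floor `1/(reps+1)`.  Every admissible table has probability
   at most the observed one, so the bound is a valid conservative p-value;
   it is what certifies genome-wide significance (5e-8) for strongly
   enriched variants whose table spaces run to 1e10 and beyond.
3. **Monte-Carlo** otherwise: tables sampled from the margin-fixed null
   (multivariate hypergeometric), `p = (count + 1)/(reps + 1)`, floored at
   `1/(reps + 1)`.  The reported p is never exactly 0.

`fisher_exact_2xC` defaults to 1e6 Monte-Carlo replicates and an
enumeration switch at 1e7 tables; `genome_scan` defaults to 1e5 replicates
and a 1e5-table switch, a per-variant cost choice for scans over thousands
of sites (the tests and the acceptance script use 2,000 replicates, which
resolves p at the 5e-4 scale — ample for calibration at α = 0.05, while
genome-wide calls ride on routes 1–2).

**FST** is `1 − H̄_S/H_T` with `H_T = 2pq` on pooled frequencies and
`H̄_S = Σ_i 2 p_i q_i f(i)`, the weights `f(i)` being each cluster's share
of counted alleles; a monomorphic site returns 0 by convention.

**Poisson regressions** `genotype ~ ancestry` (log link, intercept plus
one ancestry fraction, IRLS, Wald z p-values) are fitted separately for
the African, American and European fractions of each significant variant.
Poisson is retained for the bounded 0/1/2 response as a faithfulness
choice — it is the model the analysis specifies — although a binomial
model would also be defensible; an all-zero response is flagged rather
than fitted.

The genome-wide threshold defaults to 5e-8; 1e-8 is available by config
(both appear in the source analysis, and the discrepancy is surfaced
rather than resolved).  Fisher p and FST are computed for all variants,
Poisson fits only for significant ones.

## Annotation and diagnostic yield (`annotate`)

Annotation snapshots are local TSVs with closed vocabularies (three
pathogenicity classes; six evidence tiers).  Duplicate rows per variant
collapse to the most severe entry (pathogenic/likely pathogenic >
conflicting > uncertain; 1A > 1B > 2A > 2B > 3 > 4) — an in-package
convention, since full clinical aggregation rules are out of scope.  Scan
joins are left joins (no scan row is ever dropped); pharmacogenomic rows
with evidence in {1A, 1B, 2A, 2B} are flagged high-evidence.

Diagnostic yield for group i and class p is
`D_ip = 100 · #annotated(class p) / #observed`, where a group's observed
universe is the set of variants with at least one alternate allele seen in
the group.  This denominator makes yield genuinely ancestry-dependent;
a global-denominator variant is available by flag.

## Ancestry-specific allele frequencies (`afa`)

With Q fixed, the same allele-allocation EM restricted to the frequency
updates maximizes the binomial-mixture likelihood over `f_·j ∈ [0,1]^K`
per variant (tol 1e-6, cap 1,000 iterations; near-boundary estimates are
snapped to 0/1).  A component whose total ancestry mass `Σ_i q_ik` is
below one diploid-equivalent is flagged unreliable.  Region-level
frequencies are the linear projection `Σ_k w_k f̂_kj` through region
ancestry-composition weights, which are strictly a user/config input (the
generator can emit synthetic weights for testing).

## Pipeline and problem sizes

`run_pipeline` executes simulate → harmonize → ancestry → scan → annotate
→ afa from one TOML config (unknown keys rejected, resolved config echoed
to the output directory), writes per-stage TSVs plus a manifest with
parameters, input hashes and in/out counts, and is byte-reproducible given
(config, seed).  The bundled tests run the full pipeline on a
200-sample × 2,000-variant cohort and the estimator checks on cohorts of
150–500 samples and up to 5,000 sites — sizes at which EM recovery error
(RMSE < 0.05 supervised, < 0.08 unsupervised after alignment) and scan
calibration are already stable on a single CPU.

## Known limitations

- The exact-test Monte-Carlo route floors at `1/(reps+1)`; p-values between
  the tail bound's reach and that floor are reported at the floor.
- Poisson standard errors are mildly misspecified for the bounded genotype
  response (see above); signs and orderings, which the analysis consumes,
  are unaffected.
- No liftover: mixing genome builds is an error, not a conversion.
- No local-ancestry inference, haplotype/star-allele calling, imputation,
  or FDR machinery beyond the fixed genome-wide threshold.
- LD pruning defaults are conventions, untested against real LD structure
  (the generator produces independent variants).
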