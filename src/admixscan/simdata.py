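"""Synthetic admixed cohorts, reference panels and annotation fixtures.

The generator mirrors the admixture model that the inference stages invert:
each of K ancestral source populations (African, Indigenous American and
European, in that order) carries drifted allele frequencies drawn from a
Balding–Nichols beta distribution around a shared base frequency; every
sample owns a simplex vector of ancestry fractions drawn from a Dirichlet
centred on its cluster archetype; genotypes are binomial draws from the
ancestry-weighted allele frequency.  Variants are independent (no linkage
disequilibrium), autosomal, diploid and biallelic.

The default archetypes place three near-pure clusters at the simplex
vertices and two admixed clusters in the interior; the default cluster
weights were calibrated once so the cohort-mean ancestry is approximately
(16.7 % African, 32.8 % American, 50.6 % European).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, ValidationError, VariantRecord

__all__ = [
    "ANCESTRY_LABELS",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_CLUSTER_WEIGHTS",
    "CohortSpec",
    "AncestralFrequencies",
    "SyntheticCohort",
    "draw_ancestral_frequencies",
    "draw_cohort",
    "draw_reference_panel",
    "simulate_cohort",
    "make_annotation_fixtures",
    "make_region_weights",
    "write_cohort_vcf",
    "write_truth_table",
]

ANCESTRY_LABELS = ("AFR", "AME", "EUR")

CLINVAR_CLASSES = ("uncertain", "conflicting", "pathogenic/likely pathogenic")
PHARMGKB_LEVELS = ("1A", "1B", "2A", "2B", "3", "4")

DEFAULT_ARCHETYPES = np.array(
    [
        [0.90, 0.05, 0.05],  # AFR-like
        [0.05, 0.90, 0.05],  # AME-like
        [0.05, 0.05, 0.90],  # EUR-like
        [0.15, 0.15, 0.70],  # admixed, European-leaning
        [0.25, 0.45, 0.30],  # admixed, American-leaning with African component
    ]
)

# Calibrated so sum_c w_c * archetype_c ~= (0.167, 0.328, 0.506).
DEFAULT_CLUSTER_WEIGHTS = np.array([0.063, 0.207, 0.289, 0.250, 0.191])

# Continental-scale drift away from the shared base frequency.
DEFAULT_DRIFT = np.array([0.15, 0.20, 0.10])

_DEFAULT_PLANTED_CYCLE = np.array(
    [[0.85, 0.15, 0.15], [0.15, 0.85, 0.15], [0.15, 0.15, 0.85]]
)


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort draw.

    ``archetypes`` are the C cluster centres on the K-simplex,
    ``cluster_weights`` the sampling probability of each cluster and
    ``concentration`` the Dirichlet concentration controlling within-cluster
    spread (larger = tighter).  ``n_planted`` variants get their ancestral
    frequencies overwritten with ``planted_freqs`` rows, creating
    ancestry-enriched sites with known truth.
    """

    n_samples: int = 500
    n_variants: int = 2000
    archetypes: np.ndarray = field(default_factory=lambda: DEFAULT_ARCHETYPES.copy())
    cluster_weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLUSTER_WEIGHTS.copy()
    )
    concentration: float = 100.0
    drift: np.ndarray = field(default_factory=lambda: DEFAULT_DRIFT.copy())
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    n_planted: int = 0
    planted_freqs: np.ndarray | None = None
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.archetypes = np.asarray(self.archetypes, dtype=float)
        self.cluster_weights = np.asarray(self.cluster_weights, dtype=float)
        self.drift = np.asarray(self.drift, dtype=float)
        if self.archetypes.ndim != 2:
            raise ValidationError("archetypes must be a C x K array")
        if np.any(self.archetypes < 0) or not np.allclose(
            self.archetypes.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValidationError("archetypes must lie on the simplex")
        if len(self.cluster_weights) != len(self.archetypes):
            raise ValidationError("one weight per archetype required")
        if np.any(self.cluster_weights < 0) or not np.isclose(
            self.cluster_weights.sum(), 1.0, atol=1e-9
        ):
            raise ValidationError("cluster weights must be non-negative and sum to 1")
        if self.drift.shape != (self.n_ancestries,):
            raise ValidationError("one drift parameter per ancestral population")
        if np.any(self.drift <= 0) or np.any(self.drift >= 1):
            raise ValidationError("drift parameters must lie in (0, 1)")
        if not 0.0 <= self.missingness < 1.0:
            raise ValidationError("missingness rate must lie in [0, 1)")
        if self.n_planted:
            if self.planted_freqs is None:
                reps = -(-self.n_planted // len(_DEFAULT_PLANTED_CYCLE))
                self.planted_freqs = np.tile(_DEFAULT_PLANTED_CYCLE, (reps, 1))[
                    : self.n_planted
                ]
            self.planted_freqs = np.asarray(self.planted_freqs, dtype=float)
            if self.planted_freqs.shape != (self.n_planted, self.n_ancestries):
                raise ValidationError("planted_freqs must be n_planted x K")
            if np.any(self.planted_freqs < 0) or np.any(self.planted_freqs > 1):
                raise ValidationError("planted frequencies must lie in [0, 1]")
        if self.n_planted > self.n_variants:
            raise ValidationError("cannot plant more variants than exist")

    @property
    def n_ancestries(self) -> int:
        return self.archetypes.shape[1]


@dataclass
class AncestralFrequencies:
    """Per-population alternate-allele frequencies, one row per ancestry."""

    freqs: np.ndarray  # (K, n_variants)
    base_freq: np.ndarray  # (n_variants,)
    drift: np.ndarray  # (K,)
    planted_idx: np.ndarray  # indices of planted (overwritten) variants

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.freqs < 0) or np.any(self.freqs > 1):
            raise ValidationError("ancestral frequencies must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """A cohort draw together with its generative truth."""

    matrix: GenotypeMatrix
    q_truth: np.ndarray  # (n_samples, K)
    cluster_truth: np.ndarray  # (n_samples,) int
    freqs: AncestralFrequencies
    spec: CohortSpec

    @property
    def planted_ids(self) -> list[str]:
        vids = self.matrix.variant_ids
        return [vids[j] for j in self.freqs.planted_idx]


def draw_ancestral_frequencies(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> AncestralFrequencies:
    """Draw Balding–Nichols drifted frequencies for each ancestral population.

    Population k's frequency at variant j is
    ``Beta(p_j (1-F_k)/F_k, (1-p_j)(1-F_k)/F_k)`` around the base frequency
    ``p_j ~ Uniform(base_freq_range)``, independently across populations and
    variants.  Planted variants are then overwritten with the spec's
    divergent frequency vectors.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lo, hi = spec.base_freq_range
    p = rng.uniform(lo, hi, size=spec.n_variants)
    scale = (1.0 - spec.drift) / spec.drift  # (K,)
    a = p[None, :] * scale[:, None]
    b = (1.0 - p)[None, :] * scale[:, None]
    f = rng.beta(a, b)
    if spec.n_planted:
        planted_idx = np.sort(
            rng.choice(spec.n_variants, size=spec.n_planted, replace=False)
        )
        f[:, planted_idx] = spec.planted_freqs.T
    else:
        planted_idx = np.empty(0, dtype=int)
    return AncestralFrequencies(f, p, spec.drift.copy(), planted_idx)


def _make_records(n_variants: int) -> list[VariantRecord]:
    # Synthetic variants spread over autosomes 1..22, evenly spaced positions.
    per_chrom = -(-n_variants // 22)
    recs = []
    for j in range(n_variants):
        chrom = str(j // per_chrom + 1)
        pos = 10_000 + 1_000 * (j % per_chrom)
        recs.append(VariantRecord(chrom, pos, "A", "G"))
    return recs


def draw_cohort(
    spec: CohortSpec,
    freqs: AncestralFrequencies,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Draw genotypes plus ancestry/cluster truth tables.

    Sample i belongs to cluster c ~ Categorical(cluster_weights); its
    ancestry vector is Dirichlet(concentration * archetype_c); its genotype
    at variant j is Binomial(2, sum_k q_ik f_kj).  Missing calls are masked
    uniformly at random at the spec's rate.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n, m = spec.n_samples, spec.n_variants
    clusters = rng.choice(len(spec.cluster_weights), size=n, p=spec.cluster_weights)
    alphas = spec.concentration * spec.archetypes[clusters]
    q = rng.gamma(np.maximum(alphas, 1e-12))
    q /= q.sum(axis=1, keepdims=True)
    mix = q @ freqs.freqs  # (n, m) per-sample allele frequency
    g = rng.binomial(2, np.clip(mix, 0.0, 1.0)).astype(float)
    if spec.missingness > 0:
        g[rng.random((n, m)) < spec.missingness] = np.nan
    width = len(str(n))
    sample_ids = [f"S{i:0{width}d}" for i in range(n)]
    matrix = GenotypeMatrix(g, sample_ids, _make_records(m))
    return matrix, q, clusters


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """One-call cohort draw: frequencies, genotypes and truth tables."""
    rng = np.random.default_rng(spec.seed)
    freqs = draw_ancestral_frequencies(spec, rng)
    matrix, q, clusters = draw_cohort(spec, freqs, rng)
    return SyntheticCohort(matrix, q, clusters, freqs, spec)


def draw_reference_panel(
    freqs: AncestralFrequencies,
    n_per_pop: int = 50,
    labels: tuple[str, ...] = ANCESTRY_LABELS,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Unadmixed reference samples, ``n_per_pop`` per ancestral population.

    Returns the panel genotypes and a label table (sample_id, population).
    """
    rng = np.random.default_rng(seed)
    K, m = freqs.freqs.shape
    if len(labels) != K:
        raise ValidationError("one label per ancestral population required")
    blocks, ids, pops = [], [], []
    for k, lab in enumerate(labels):
        blocks.append(rng.binomial(2, freqs.freqs[k], size=(n_per_pop, m)).astype(float))
        ids.extend(f"REF_{lab}_{i:03d}" for i in range(n_per_pop))
        pops.extend([lab] * n_per_pop)
    matrix = GenotypeMatrix(np.vstack(blocks), ids, _make_records(m))
    return matrix, pd.DataFrame({"sample_id": ids, "population": pops})


def make_annotation_fixtures(
    variant_ids: list[str],
    planted_ids: list[str],
    clinvar_fraction: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sparse ClinVar-like and PharmGKB-like annotation snapshots.

    A ``clinvar_fraction`` of all variants receives one of the three
    pathogenicity classes (uncertain, conflicting, pathogenic/likely
    pathogenic); every planted variant receives a pharmacogenomic record
    with an evidence level drawn from the PharmGKB tiers 1A..4.
    """
    known = set(variant_ids)
    for vid in planted_ids:
        if vid not in known:
            raise ValidationError(f"planted id {vid!r} not among cohort variants")
    if not 0.0 <= clinvar_fraction <= 1.0:
        raise ValidationError("clinvar_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_annot = round(clinvar_fraction * len(variant_ids))
    chosen = sorted(rng.choice(len(variant_ids), size=n_annot, replace=False))
    # Class mix loosely follows clinical databases: uncertain most common,
    # pathogenic rarest.
    classes = rng.choice(CLINVAR_CLASSES, size=n_annot, p=[0.6, 0.3, 0.1])
    clinvar = pd.DataFrame(
        {
            "variant_id": [variant_ids[j] for j in chosen],
            "rsid": [f"rs9{j:06d}" for j in chosen],
            "gene": [f"GENE{j % 97}" for j in chosen],
            "classification": classes,
            "phenotype": [f"phenotype_{j % 23}" for j in chosen],
        }
    )
    levels = rng.choice(PHARMGKB_LEVELS, size=len(planted_ids))
    pharmgkb = pd.DataFrame(
        {
            "variant_id": list(planted_ids),
            "rsid": [f"rs8{i:06d}" for i in range(len(planted_ids))],
            "gene": [f"PGX{i % 11}" for i in range(len(planted_ids))],
            "evidence_level": levels,
            "drug": [f"drug_{i % 9}" for i in range(len(planted_ids))],
        }
    )
    return clinvar, pharmgkb


def make_region_weights(
    regions: list[str] | int = 8, seed: int = 0, alpha: float = 2.0
) -> pd.DataFrame:
    """Synthetic region (department) ancestry-composition weights.

    Each region gets a Dirichlet(alpha) simplex vector over AFR/AME/EUR.
    """
    if isinstance(regions, int):
        regions = [f"region_{i:02d}" for i in range(regions)]
    rng = np.random.default_rng(seed)
    w = rng.dirichlet([alpha] * len(ANCESTRY_LABELS), size=len(regions))
    out = pd.DataFrame(w, columns=[f"w_{a}" for a in ANCESTRY_LABELS])
    out.insert(0, "region", regions)
    return out


_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_cohort_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a minimal, deterministic VCF 4.2 with GT-only genotype fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##genome_build={matrix.build}\n")
        seen: list[str] = []
        for rec in matrix.records:
            if rec.chrom not in seen:
                seen.append(rec.chrom)
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, rec in enumerate(matrix.records):
            col = matrix.dosages[:, j]
            gts = "\t".join(
                "./." if np.isnan(g) else _GT_CODES[g] for g in col
            )
            rid = rec.rsid or "."
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rid}\t{rec.ref}\t{rec.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_truth_table(q: np.ndarray, clusters: np.ndarray, sample_ids: list[str], path: str) -> None:
    """Truth table TSV: sample_id, q_AFR, q_AME, q_EUR, cluster."""
    df = pd.DataFrame(q, columns=[f"q_{a}" for a in ANCESTRY_LABELS])
    df.insert(0, "sample_id", sample_ids)
    df["cluster"] = clusters
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
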