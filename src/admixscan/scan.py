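"""Ancestry-enrichment scan: exact 2xC allele-count test, FST, Poisson models.

For every variant the scan tabulates reference and alternate allele counts
across the categorical ancestry clusters (a 2 x C contingency table),
computes a two-sided Fisher exact p-value under the probability-ordering
criterion, the multi-group fixation index

    FST = 1 - H_S_bar / H_T,      H_T = 2 p q,   H_S_bar = sum_i 2 p_i q_i f(i),

with f(i) the fraction of (non-missing) alleles contributed by cluster i,
and — for variants passing the genome-wide threshold — three Poisson
regressions of genotype on the African, American and European ancestry
fractions.

Exact p-values are computed by full enumeration of the margin-fixed table
space whenever the space is small enough (the exact table count is obtained
first by dynamic programming).  For large tables the scan falls back to
Monte-Carlo sampling from the margin-fixed null, except when the observed
table is so extreme that the deterministic tail bound

    p <= (#tables with the observed margins) * Pr(observed table)

already certifies significance far below anything Monte-Carlo could
resolve; the bound is then reported as a conservative p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln
from scipy.stats import multivariate_hypergeom

from .core import GenotypeMatrix, ValidationError

__all__ = [
    "ClusterAlleleCounts",
    "PoissonResult",
    "cluster_allele_counts",
    "fisher_exact_2xC",
    "count_tables",
    "fst",
    "poisson_assoc",
    "genome_scan",
]

_PMF_TOL = 1e-7  # relative slack when comparing table probabilities


@dataclass
class ClusterAlleleCounts:
    """Reference/alternate allele counts per ancestry cluster."""

    cluster_names: list[str]
    ref: np.ndarray  # (C,) non-negative ints
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        if np.any(self.ref < 0) or np.any(self.alt < 0):
            raise ValidationError("allele counts must be non-negative")
        if not (len(self.cluster_names) == len(self.ref) == len(self.alt)):
            raise ValidationError("one (ref, alt) pair per cluster required")

    @property
    def totals(self) -> np.ndarray:
        return self.ref + self.alt

    @property
    def N(self) -> int:
        return int(self.totals.sum())

    @property
    def weights(self) -> np.ndarray:
        """f(i): fraction of all counted alleles contributed by cluster i."""
        return self.totals / self.N

    @property
    def q_i(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.totals > 0, self.alt / self.totals, np.nan)

    @property
    def p_i(self) -> np.ndarray:
        return 1.0 - self.q_i

    @property
    def pooled_q(self) -> float:
        return float(self.alt.sum() / self.N)

    def enriched_cluster(self) -> str:
        """Cluster with the highest alternate allele frequency."""
        return self.cluster_names[int(np.nanargmax(self.q_i))]


def cluster_allele_counts(
    matrix: GenotypeMatrix, labels: np.ndarray, variant: str | int
) -> ClusterAlleleCounts:
    """Tabulate ref/alt allele counts per cluster for one variant.

    Missing genotypes contribute no alleles.  Clusters with zero non-missing
    calls are dropped with a warning (the test becomes 2 x (C-1)).
    """
    labels = np.asarray(labels)
    if len(labels) != matrix.n_samples:
        raise ValidationError("one cluster label per sample required")
    j = matrix.variant_index(variant) if isinstance(variant, str) else int(variant)
    col = matrix.dosages[:, j]
    names, refs, alts = [], [], []
    for name in pd.unique(labels):
        g = col[labels == name]
        g = g[~np.isnan(g)]
        if g.size == 0:
            warnings.warn(f"cluster {name!r} has no calls at variant {variant}; dropped")
            continue
        alt = int(g.sum())
        names.append(str(name))
        alts.append(alt)
        refs.append(2 * g.size - alt)
    return ClusterAlleleCounts(names, np.array(refs), np.array(alts))


def count_tables(col_totals: np.ndarray, row1_total: int) -> float:
    """Number of 2xC tables with the given margins (DP convolution).

    Exact for counts below 2^53; returned as float since table spaces can
    exceed integer precision (only magnitudes matter to the callers).
    """
    counts = np.zeros(row1_total + 1)
    counts[0] = 1.0
    for N_i in col_totals:
        hi = min(int(N_i), row1_total)
        counts = np.convolve(counts, np.ones(hi + 1))[: row1_total + 1]
    return float(counts[row1_total])


def _enumerate_logps(
    col_totals: np.ndarray, R: int, chunk: int = 1 << 16
) -> np.ndarray:
    """log prod C(N_i, x_i) for every feasible first-row vector x, vectorized.

    Expansion is chunked over partial states to bound peak memory.
    """
    sums = np.zeros(1, dtype=np.int64)
    logps = np.zeros(1)
    suffix_cap = np.concatenate([np.cumsum(col_totals[::-1])[::-1], [0]])
    for i, N_i in enumerate(col_totals):
        x = np.arange(min(int(N_i), R) + 1)
        logc = gammaln(N_i + 1) - gammaln(x + 1) - gammaln(N_i - x + 1)
        parts_s, parts_l = [], []
        for lo in range(0, sums.size, chunk):
            s = sums[lo : lo + chunk]
            l = logps[lo : lo + chunk]
            new_sums = (s[:, None] + x[None, :]).ravel()
            new_logps = (l[:, None] + logc[None, :]).ravel()
            ok = (new_sums <= R) & (R - new_sums <= suffix_cap[i + 1])
            parts_s.append(new_sums[ok])
            parts_l.append(new_logps[ok])
        sums = np.concatenate(parts_s)
        logps = np.concatenate(parts_l)
    return logps  # all have sums == R by the capacity constraint


def fisher_exact_2xC(
    table: ClusterAlleleCounts,
    method: str = "auto",
    mc_reps: int = 1_000_000,
    seed: int | None = None,
    enum_max: int = 10_000_000,
) -> float:
    """Two-sided exact test of homogeneous allele frequencies across clusters.

    The p-value is the total conditional probability (margins fixed) of all
    tables no more probable than the one observed.  ``method``:

    * ``"exact"`` — full enumeration of the table space, regardless of size.
    * ``"montecarlo"`` — sample ``mc_reps`` tables from the margin-fixed
      null; p = (count + 1) / (reps + 1), floored at 1/(reps + 1).
    * ``"auto"`` — enumeration when the exact table count is at most
      ``enum_max``; otherwise the deterministic bound
      ``n_tables * pmf(observed)`` if it resolves below the Monte-Carlo
      floor, else Monte-Carlo.

    The p-value is never exactly 0.
    """
    nonzero = table.totals > 0
    if not nonzero.all():
        warnings.warn("dropping zero-total cluster columns from the Fisher table")
        table = ClusterAlleleCounts(
            [n for n, k in zip(table.cluster_names, nonzero) if k],
            table.ref[nonzero],
            table.alt[nonzero],
        )
    if len(table.ref) < 2:
        raise ValidationError("Fisher test needs at least 2 cluster columns")
    if table.ref.sum() == 0 or table.alt.sum() == 0:
        warnings.warn("degenerate table (an all-zero allele row); p = 1")
        return 1.0
    cols = table.totals
    # condition on the smaller row for a smaller enumeration space
    if table.ref.sum() <= table.alt.sum():
        row, R = table.ref, int(table.ref.sum())
    else:
        row, R = table.alt, int(table.alt.sum())
    N = int(cols.sum())
    log_denom = gammaln(N + 1) - gammaln(R + 1) - gammaln(N - R + 1)
    obs_logp = float(
        np.sum(gammaln(cols + 1) - gammaln(row + 1) - gammaln(cols - row + 1))
    )

    def _exact() -> float:
        logps = _enumerate_logps(cols, R)
        mask = logps <= obs_logp + _PMF_TOL
        return float(np.exp(logps[mask] - log_denom).sum())

    def _mc() -> float:
        rng = np.random.default_rng(seed)
        draws = multivariate_hypergeom.rvs(cols, R, size=mc_reps, random_state=rng)
        logpmf = multivariate_hypergeom.logpmf(draws, cols, R)
        hits = int(np.sum(logpmf <= obs_logp - log_denom + _PMF_TOL))
        return (hits + 1) / (mc_reps + 1)

    if method == "exact":
        return min(_exact(), 1.0)
    if method == "montecarlo":
        return _mc()
    if method != "auto":
        raise ValidationError(f"unknown method {method!r}")
    n_tables = count_tables(cols, R)
    if n_tables <= enum_max:
        return min(_exact(), 1.0)
    # conservative deterministic bound: every admissible table is at most as
    # probable as the observed one, so p <= n_tables * pmf(observed)
    log_bound = np.log(n_tables) + obs_logp - log_denom
    if log_bound < -np.log(mc_reps + 1):
        return float(max(np.exp(log_bound), 5e-324))
    return _mc()


def fst(table: ClusterAlleleCounts) -> float:
    """Multi-group fixation index 1 - H_S_bar / H_T.

    Total heterozygosity uses the pooled allele frequencies; the mean
    within-cluster heterozygosity weights each cluster by its share of
    counted alleles.  A monomorphic site returns 0 by convention.
    """
    if table.N == 0:
        raise ValidationError("empty allele-count table")
    q = table.pooled_q
    h_t = 2.0 * (1.0 - q) * q
    if h_t == 0.0:
        return 0.0
    qi = np.nan_to_num(table.q_i, nan=0.0)
    h_s = float(np.sum(2.0 * (1.0 - qi) * qi * table.weights))
    return 1.0 - h_s / h_t


@dataclass
class PoissonResult:
    """One genotype ~ ancestry Poisson fit."""

    beta: float
    se: float
    p: float
    intercept: float
    converged: bool
    ok: bool
    note: str = ""


def poisson_assoc(dosages: np.ndarray, ancestry: np.ndarray) -> PoissonResult:
    """Poisson regression of alternate-allele dosage on one ancestry fraction.

    Log link, intercept plus a single covariate, fitted by IRLS; the p-value
    is the Wald z-test on the ancestry coefficient.  Missing dosages are
    dropped pairwise.  An all-zero response has no finite MLE and is flagged
    rather than fitted.
    """
    dosages = np.asarray(dosages, dtype=float)
    ancestry = np.asarray(ancestry, dtype=float)
    keep = ~np.isnan(dosages)
    y, x = dosages[keep], ancestry[keep]
    if y.size < 10:
        raise ValidationError(f"need >= 10 non-missing pairs, got {y.size}")
    if np.any((x < 0) | (x > 1)):
        raise ValidationError("ancestry fractions must lie in [0, 1]")
    if np.all(y == 0):
        return PoissonResult(np.nan, np.nan, np.nan, np.nan, False, False, "all-zero dosage")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200, tol=1e-12)
    converged = bool(res.converged)
    if not converged:
        return PoissonResult(
            float(res.params[1]), float(res.bse[1]), float(res.pvalues[1]),
            float(res.params[0]), False, False, "did not converge",
        )
    return PoissonResult(
        float(res.params[1]),
        float(res.bse[1]),
        float(res.pvalues[1]),
        float(res.params[0]),
        True,
        True,
    )


def genome_scan(
    matrix: GenotypeMatrix,
    labels: np.ndarray,
    Q: np.ndarray,
    threshold: float = 5e-8,
    method: str = "auto",
    mc_reps: int = 100_000,
    seed: int | None = None,
    enum_max: int = 100_000,
    ancestry_labels: tuple[str, ...] = ("AFR", "AME", "EUR"),
) -> pd.DataFrame:
    """Per-variant enrichment scan over all variants of a cohort.

    Every variant gets a Fisher p-value, FST and its enriched cluster (the
    one with the highest alternate allele frequency); variants below
    ``threshold`` additionally get one Poisson genotype ~ ancestry fit per
    ancestry component.  Per-variant failures are recorded and the scan
    continues.  Results are sorted by Fisher p ascending.
    """
    Q = np.asarray(Q, dtype=float)
    labels = np.asarray(labels)
    if Q.shape != (matrix.n_samples, len(ancestry_labels)):
        raise ValidationError("Q must be n_samples x K")
    rng = np.random.default_rng(seed)
    rows = []
    for j, rec in enumerate(matrix.records):
        row: dict = {
            "variant_id": rec.canonical_id,
            "rsid": rec.rsid,
            "chrom": rec.chrom,
            "pos": rec.pos,
        }
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                counts = cluster_allele_counts(matrix, labels, j)
                p = fisher_exact_2xC(
                    counts,
                    method=method,
                    mc_reps=mc_reps,
                    seed=int(rng.integers(2**31 - 1)),
                    enum_max=enum_max,
                )
            row.update(
                allele_count=counts.N,
                fisher_p=p,
                fst=fst(counts),
                enriched_cluster=counts.enriched_cluster(),
                significant=p < threshold,
                error="",
            )
        except (ValidationError, ValueError) as exc:  # scan continues
            row.update(
                allele_count=np.nan, fisher_p=np.nan, fst=np.nan,
                enriched_cluster="", significant=False, error=str(exc),
            )
            rows.append(row)
            continue
        if row["significant"]:
            for k, anc in enumerate(ancestry_labels):
                try:
                    fit = poisson_assoc(matrix.dosages[:, j], Q[:, k])
                    row[f"beta_{anc}"] = fit.beta
                    row[f"se_{anc}"] = fit.se
                    row[f"p_{anc}"] = fit.p
                except ValidationError as exc:
                    row[f"beta_{anc}"] = np.nan
                    row[f"se_{anc}"] = np.nan
                    row[f"p_{anc}"] = np.nan
                    row["error"] = str(exc)
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values("fisher_p", kind="stable").reset_index(drop=True)
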