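import itertools
import math
import warnings

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from admixscan.core import ValidationError
from admixscan.scan import (
    ClusterAlleleCounts,
    cluster_allele_counts,
    count_tables,
    fisher_exact_2xC,
    fst,
    genome_scan,
    poisson_assoc,
)
from admixscan.simdata import CohortSpec, simulate_cohort
from admixscan.ancestry import ElbowKMeans, name_clusters


def brute_force_fisher(ref, alt):
    """Independent oracle: exhaust all margin-fixed tables by direct product."""
    cols = [r + a for r, a in zip(ref, alt)]
    R = sum(ref)

    def prob(xs):
        num = math.prod(math.comb(c, x) for c, x in zip(cols, xs))
        return num / math.comb(sum(cols), R)

    obs = prob(ref)
    total = 0.0
    for xs in itertools.product(*(range(c + 1) for c in cols)):
        if sum(xs) != R:
            continue
        p = prob(xs)
        if p <= obs * (1 + 1e-7):
            total += p
    return total


def random_tables(n, max_margin=20, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        C = int(rng.integers(2, 6))
        ref = rng.integers(0, max_margin + 1, C)
        alt = rng.integers(0, max_margin + 1, C)
        if ref.sum() == 0 or alt.sum() == 0 or np.any(ref + alt == 0):
            continue
        out.append((ref, alt))
    return out


class TestClusterAlleleCounts:
    def test_dosage_arithmetic(self, toy_matrix):
        labels = np.array(["a"] * 3 + ["b"] * 5)
        toy_matrix.dosages[:3, 0] = [0.0, 1.0, 2.0]
        t = cluster_allele_counts(toy_matrix, labels, 0)
        i = t.cluster_names.index("a")
        assert t.ref[i] == 3 and t.alt[i] == 3

    def test_missing_genotype_contributes_no_alleles(self, toy_matrix):
        labels = np.array(["a"] * 3 + ["b"] * 5)
        toy_matrix.dosages[:3, 1] = [1.0, np.nan, 2.0]
        t = cluster_allele_counts(toy_matrix, labels, 1)
        i = t.cluster_names.index("a")
        assert t.totals[i] == 4

    def test_total_allele_count_matches_matrix_tally(self, small_cohort):
        labels = np.array(["c%d" % (i % 5) for i in range(small_cohort.matrix.n_samples)])
        t = cluster_allele_counts(small_cohort.matrix, labels, 0)
        col = small_cohort.matrix.dosages[:, 0]
        assert t.N == 2 * int((~np.isnan(col)).sum())

    def test_empty_cluster_column_dropped_with_warning(self, toy_matrix):
        labels = np.array(["a"] * 7 + ["b"])
        toy_matrix.dosages[7, 2] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            t = cluster_allele_counts(toy_matrix, labels, 2)
        assert t.cluster_names == ["a"]


class TestFisherExact:
    def test_symmetric_2x2_diagonal_is_one(self):
        t = ClusterAlleleCounts(["a", "b"], np.array([1, 0]), np.array([0, 1]))
        assert fisher_exact_2xC(t) == pytest.approx(1.0)

    def test_two_by_two_hand_enumeration(self):
        # margins (2,2): table probs {1/6, 4/6, 1/6}; observed 1/6 -> p = 1/3
        t = ClusterAlleleCounts(["a", "b"], np.array([2, 0]), np.array([0, 2]))
        assert fisher_exact_2xC(t) == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_brute_force_on_random_tables(self):
        for ref, alt in random_tables(200, seed=1):
            t = ClusterAlleleCounts([str(i) for i in range(len(ref))], ref, alt)
            p = fisher_exact_2xC(t, method="exact")
            assert p == pytest.approx(brute_force_fisher(list(ref), list(alt)), abs=1e-12)

    def test_matches_classical_hypergeometric_on_2x2(self):
        for ref, alt in random_tables(100, seed=2):
            if len(ref) != 2:
                continue
            t = ClusterAlleleCounts(["a", "b"], ref, alt)
            p_scipy = scipy_fisher(np.array([ref, alt]))[1]
            assert fisher_exact_2xC(t, method="exact") == pytest.approx(p_scipy, rel=1e-9)

    def test_montecarlo_agrees_with_exact_within_three_se(self):
        reps = 20_000
        devs = []
        for ref, alt in random_tables(30, seed=3):
            t = ClusterAlleleCounts([str(i) for i in range(len(ref))], ref, alt)
            p_ex = fisher_exact_2xC(t, method="exact")
            p_mc = fisher_exact_2xC(t, method="montecarlo", mc_reps=reps, seed=4)
            se = math.sqrt(p_ex * (1 - p_ex) / reps) + 1 / reps
            devs.append(abs(p_mc - p_ex) / se)
        # joint check: isolated 3-SE exceedances are expected across 30 tables
        assert max(devs) <= 4.0
        assert np.mean(np.array(devs) <= 3.0) >= 0.9

    def test_column_permutation_leaves_p_unchanged(self):
        ref, alt = np.array([5, 1, 9, 3]), np.array([2, 8, 1, 6])
        t1 = ClusterAlleleCounts(list("abcd"), ref, alt)
        perm = [2, 0, 3, 1]
        t2 = ClusterAlleleCounts(list("cadb"), ref[perm], alt[perm])
        assert fisher_exact_2xC(t1) == pytest.approx(fisher_exact_2xC(t2), abs=1e-12)

    def test_ref_alt_swap_leaves_p_and_fst_unchanged(self):
        ref, alt = np.array([5, 1, 9]), np.array([2, 8, 1])
        t1 = ClusterAlleleCounts(list("abc"), ref, alt)
        t2 = ClusterAlleleCounts(list("abc"), alt, ref)
        assert fisher_exact_2xC(t1) == pytest.approx(fisher_exact_2xC(t2), abs=1e-12)
        assert fst(t1) == pytest.approx(fst(t2), abs=1e-12)

    def test_degenerate_all_zero_row_returns_one(self):
        t = ClusterAlleleCounts(["a", "b"], np.array([4, 6]), np.array([0, 0]))
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2xC(t) == 1.0

    def test_large_extreme_table_resolved_by_tail_bound(self):
        # far beyond enumeration: the deterministic bound must certify p
        ref = np.array([500, 20, 480, 490, 470])
        alt = np.array([10, 490, 30, 20, 40])
        t = ClusterAlleleCounts(list("abcde"), ref, alt)
        p = fisher_exact_2xC(t, method="auto", mc_reps=1000, enum_max=10_000)
        assert 0 < p < 5e-8

    def test_count_tables_matches_direct_enumeration(self):
        for ref, alt in random_tables(20, max_margin=6, seed=5):
            cols = ref + alt
            R = int(ref.sum())
            direct = sum(
                1
                for xs in itertools.product(*(range(c + 1) for c in cols))
                if sum(xs) == R
            )
            assert count_tables(cols, R) == pytest.approx(direct)


class TestFst:
    def test_equal_frequencies_give_zero(self):
        t = ClusterAlleleCounts(list("abc"), np.array([7, 7, 7]), np.array([3, 3, 3]))
        assert fst(t) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_gives_one(self):
        t = ClusterAlleleCounts(["a", "b"], np.array([10, 0]), np.array([0, 10]))
        assert fst(t) == pytest.approx(1.0, abs=1e-12)

    def test_two_cluster_textbook_value(self):
        # q = (0.1, 0.5) equal weights: H_T = 0.42, H_S = 0.34
        t = ClusterAlleleCounts(["a", "b"], np.array([9, 5]), np.array([1, 5]))
        assert fst(t) == pytest.approx(1 - 0.34 / 0.42, abs=1e-12)

    def test_monomorphic_site_is_zero_by_convention(self):
        t = ClusterAlleleCounts(["a", "b"], np.array([8, 6]), np.array([0, 0]))
        assert fst(t) == 0.0


def newton_poisson(y, x):
    """Independent Newton-Raphson maximizer of the Poisson log-likelihood."""
    X = np.column_stack([np.ones_like(x), x])
    b = np.zeros(2)
    for _ in range(200):
        mu = np.exp(X @ b)
        grad = X.T @ (y - mu)
        if np.abs(grad).max() < 1e-12:
            break
        b = b + np.linalg.solve(X.T @ (mu[:, None] * X), grad)
    return b


class TestPoisson:
    def test_constant_dosage_one_gives_null_fit(self):
        fit = poisson_assoc(np.ones(20), np.linspace(0, 1, 20))
        assert fit.beta == pytest.approx(0.0, abs=1e-8)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_matches_newton_raphson_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(15, 60))
            x = rng.random(n)
            y = np.clip(rng.poisson(np.exp(-0.3 + 0.9 * x)), 0, 2).astype(float)
            if y.sum() == 0:
                continue
            fit = poisson_assoc(y, x)
            b0, b1 = newton_poisson(y, x)
            assert fit.intercept == pytest.approx(b0, abs=1e-6)
            assert fit.beta == pytest.approx(b1, abs=1e-6)

    def test_all_zero_dosage_flagged_not_fitted(self):
        fit = poisson_assoc(np.zeros(15), np.linspace(0, 1, 15))
        assert not fit.ok and np.isnan(fit.beta)

    def test_ref_alt_swap_negates_beta(self):
        rng = np.random.default_rng(2)
        x = rng.random(40)
        y = rng.binomial(2, 0.2 + 0.5 * x).astype(float)
        b_fwd = poisson_assoc(y, x).beta
        b_rev = poisson_assoc(2.0 - y, x).beta
        assert np.sign(b_fwd) == -np.sign(b_rev)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            poisson_assoc(np.ones(5), np.linspace(0, 1, 5))


class TestGenomeScan:
    @staticmethod
    def _clusters(cohort):
        km = ElbowKMeans(random_state=0).fit(cohort.q_truth)
        names = name_clusters(km.cluster_means_)
        return np.array([names[c] for c in km.labels_], dtype=object)

    def test_planted_variants_flagged_with_correct_cluster(self, planted_cohort):
        names = self._clusters(planted_cohort)
        res = genome_scan(
            planted_cohort.matrix, names, planted_cohort.q_truth,
            mc_reps=2000, seed=5,
        )
        planted = set(planted_cohort.planted_ids)
        sub = res[res.variant_id.isin(planted)]
        assert sub["significant"].all()
        anc = ("AFR", "AME", "EUR")
        vids = planted_cohort.matrix.variant_ids
        for row in sub.itertuples():
            k = int(np.argmax(planted_cohort.freqs.freqs[:, vids.index(row.variant_id)]))
            assert row.enriched_cluster == f"{anc[k]}-like"
            assert getattr(row, f"beta_{anc[k]}") > 0

    def test_threshold_one_reports_every_variant_with_regressions(self, planted_cohort):
        names = self._clusters(planted_cohort)
        few = planted_cohort.matrix.take_variants(np.arange(15))
        res = genome_scan(
            few, names, planted_cohort.q_truth,
            threshold=1.0, mc_reps=500, seed=6,
        )
        assert len(res) == 15
        assert res["significant"].all()
        assert res["fisher_p"].is_monotonic_increasing

    def test_planted_fst_exceeds_null_fst(self, planted_cohort):
        names = self._clusters(planted_cohort)
        res = genome_scan(
            planted_cohort.matrix, names, planted_cohort.q_truth,
            mc_reps=500, seed=7,
        )
        planted = set(planted_cohort.planted_ids)
        fst_planted = res[res.variant_id.isin(planted)]["fst"].median()
        fst_null = res[~res.variant_id.isin(planted)]["fst"].median()
        assert fst_planted > fst_null
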