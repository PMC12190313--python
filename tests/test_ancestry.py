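import numpy as np
import pytest

from admixscan.ancestry import (
    AdmixtureEM,
    ElbowKMeans,
    ReferencePCA,
    align_components,
    name_clusters,
)
from admixscan.core import ValidationError
from admixscan.simdata import (
    CohortSpec,
    draw_reference_panel,
    simulate_cohort,
)


class TestReferencePCA:
    @staticmethod
    def _two_pop_panel():
        rng = np.random.default_rng(0)
        fa = rng.uniform(0.05, 0.3, 200)
        fb = rng.uniform(0.7, 0.95, 200)
        ga = rng.binomial(2, fa, size=(10, 200)).astype(float)
        gb = rng.binomial(2, fb, size=(10, 200)).astype(float)
        return np.vstack([ga, gb])

    def test_pc1_separates_diverged_populations(self):
        # oracle: direct eigendecomposition of the standardized covariance
        G = self._two_pop_panel()
        pca = ReferencePCA(n_components=3).fit(G)
        coords = pca.coordinates_
        assert np.sign(coords[:10, 0].mean()) != np.sign(coords[10:, 0].mean())
        p = G.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        Z = (G[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        evals = np.linalg.eigvalsh(Z @ Z.T)[::-1]
        np.testing.assert_allclose(
            pca.singular_values_[:3] ** 2, evals[:3], rtol=1e-8
        )

    def test_percent_variance_sums_to_hundred(self):
        pca = ReferencePCA().fit(self._two_pop_panel())
        assert pca.percent_variance_.sum() == pytest.approx(100.0)

    def test_reference_reprojection_reproduces_fitted_coordinates(self):
        G = self._two_pop_panel()
        pca = ReferencePCA(n_components=4).fit(G)
        np.testing.assert_allclose(pca.transform(G), pca.coordinates_, atol=1e-8)

    def test_duplicated_sample_maps_to_identical_coordinates(self):
        G = self._two_pop_panel()
        pca = ReferencePCA(n_components=2).fit(G)
        dup = pca.transform(np.vstack([G[0], G[0]]))
        np.testing.assert_allclose(dup[0], dup[1])

    def test_all_monomorphic_panel_rejected(self):
        with pytest.raises(ValidationError):
            ReferencePCA().fit(np.zeros((5, 10)))

    def test_low_site_overlap_rejected(self):
        c = simulate_cohort(CohortSpec(n_samples=30, n_variants=100, seed=1))
        ref, _ = draw_reference_panel(c.freqs, n_per_pop=10, seed=2)
        pca = ReferencePCA(n_components=2).fit(ref)
        few = c.matrix.take_variants(np.arange(10))
        with pytest.raises(ValidationError, match="shares"):
            pca.transform(few)

    def test_pure_ancestry_samples_project_with_their_reference(self):
        # construction oracle: unadmixed AFR cohort lands in the AFR corner
        spec = CohortSpec(
            n_samples=25,
            n_variants=300,
            archetypes=np.array([[1.0, 0.0, 0.0]]),
            cluster_weights=np.array([1.0]),
            concentration=1e9,
            seed=3,
        )
        c = simulate_cohort(spec)
        ref, labels = draw_reference_panel(c.freqs, n_per_pop=25, seed=4)
        pca = ReferencePCA(n_components=2).fit(ref)
        proj = pca.transform(c.matrix)
        ref_coords = pca.coordinates_
        pops = labels["population"].to_numpy()
        d = {
            pop: np.linalg.norm(
                proj.mean(axis=0) - ref_coords[pops == pop].mean(axis=0)
            )
            for pop in ("AFR", "AME", "EUR")
        }
        assert d["AFR"] == min(d.values())


class TestAdmixtureEM:
    def test_single_component_recovers_site_frequencies(self, small_cohort):
        est = AdmixtureEM(n_components=1, random_state=0).fit(small_cohort.matrix)
        np.testing.assert_allclose(est.Q_, 1.0)
        np.testing.assert_allclose(
            est.components_[0], small_cohort.matrix.alt_freq(), atol=1e-4
        )

    def test_supervised_recovery_and_monotone_loglik(self, small_cohort):
        est = AdmixtureEM(mode="supervised", random_state=0).fit(
            small_cohort.matrix, reference_freqs=small_cohort.freqs.freqs
        )
        rmse = np.sqrt(np.mean((est.Q_ - small_cohort.q_truth) ** 2))
        assert rmse < 0.08  # 400 sites; tightens with more sites
        diffs = np.diff(est.loglik_trace_)
        assert (diffs >= -1e-8).all()

    def test_simplex_constraint_holds_every_iteration(self, small_cohort):
        # run a handful of single iterations manually via max_iter stepping
        for iters in (1, 3, 7):
            est = AdmixtureEM(
                mode="supervised", max_iter=iters, random_state=0
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(small_cohort.matrix, reference_freqs=small_cohort.freqs.freqs)
            np.testing.assert_allclose(est.Q_.sum(axis=1), 1.0, atol=1e-9)

    def test_sample_order_equivariance(self, small_cohort):
        # fixed iteration count: the adaptive stop keys on the summed
        # log-likelihood, whose float value depends on summation order
        import warnings

        perm = np.random.default_rng(5).permutation(small_cohort.matrix.n_samples)
        kw = dict(mode="supervised", tol=-1.0, max_iter=150, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est1 = AdmixtureEM(**kw).fit(
                small_cohort.matrix, reference_freqs=small_cohort.freqs.freqs
            )
            est2 = AdmixtureEM(**kw).fit(
                small_cohort.matrix.take_samples(perm),
                reference_freqs=small_cohort.freqs.freqs,
            )
        np.testing.assert_allclose(est1.Q_[perm], est2.Q_, atol=1e-10)

    def test_recovery_improves_with_more_sites(self):
        rmses = {}
        for m in (100, 1000):
            c = simulate_cohort(CohortSpec(n_samples=80, n_variants=m, seed=6))
            est = AdmixtureEM(mode="supervised", random_state=0).fit(
                c.matrix, reference_freqs=c.freqs.freqs
            )
            rmses[m] = np.sqrt(np.mean((est.Q_ - c.q_truth) ** 2))
        assert rmses[1000] < rmses[100]

    def test_supervised_requires_reference(self, small_cohort):
        with pytest.raises(ValidationError):
            AdmixtureEM(mode="supervised").fit(small_cohort.matrix)


class TestAlignComponents:
    @staticmethod
    def _fit(small_cohort):
        est = AdmixtureEM(mode="supervised", random_state=0).fit(
            small_cohort.matrix, reference_freqs=small_cohort.freqs.freqs
        )
        pops = np.array([""] * small_cohort.matrix.n_samples, dtype=object)
        for k, lab in enumerate(("AFR", "AME", "EUR")):
            pops[np.argsort(-small_cohort.q_truth[:, k])[:8]] = lab
        return est, pops

    def test_aligned_input_gets_identity_permutation(self, small_cohort):
        est, pops = self._fit(small_cohort)
        _, _, perm = align_components(est.Q_, est.components_, pops)
        np.testing.assert_array_equal(perm, [0, 1, 2])

    def test_swap_recovers_inverse_permutation(self, small_cohort):
        est, pops = self._fit(small_cohort)
        order = [2, 0, 1]
        Q, F, perm = align_components(
            est.Q_[:, order], est.components_[order], pops
        )
        np.testing.assert_allclose(Q, est.Q_)
        np.testing.assert_allclose(F, est.components_)

    def test_missing_reference_population_rejected(self, small_cohort):
        est, pops = self._fit(small_cohort)
        pops[pops == "EUR"] = ""
        with pytest.raises(ValidationError, match="EUR"):
            align_components(est.Q_, est.components_, pops)


class TestElbowKMeans:
    def test_five_archetype_cohort_selects_five_clusters(self):
        c = simulate_cohort(CohortSpec(n_samples=400, n_variants=10, seed=12))
        km = ElbowKMeans(random_state=0).fit(c.q_truth)
        assert km.n_clusters_ == 5

    def test_two_archetype_cohort_selects_two_clusters(self):
        spec = CohortSpec(
            n_samples=400,
            n_variants=10,
            archetypes=np.array([[0.9, 0.05, 0.05], [0.05, 0.05, 0.9]]),
            cluster_weights=np.array([0.5, 0.5]),
            seed=13,
        )
        km = ElbowKMeans(random_state=0).fit(simulate_cohort(spec).q_truth)
        assert km.n_clusters_ == 2

    def test_sse_non_increasing_in_k(self):
        c = simulate_cohort(CohortSpec(n_samples=200, n_variants=10, seed=14))
        km = ElbowKMeans(n_init=20, random_state=0).fit(c.q_truth)
        assert (np.diff(km.sse_) <= 1e-6 * km.sse_[0]).all()

    def test_every_cluster_non_empty(self):
        c = simulate_cohort(CohortSpec(n_samples=300, n_variants=10, seed=15))
        km = ElbowKMeans(random_state=0).fit(c.q_truth)
        assert len(np.unique(km.labels_)) == km.n_clusters_


class TestNameClusters:
    def test_predominant_cluster_gets_like_suffix(self):
        names = name_clusters(np.array([[0.9, 0.05, 0.05], [0.3, 0.4, 0.3]]))
        assert names == ["AFR-like", "ADX1"]

    def test_admixed_clusters_ordered_by_european_fraction(self):
        means = np.array(
            [
                [0.05, 0.05, 0.9],   # EUR-like
                [0.25, 0.45, 0.3],   # less European admixed -> ADX2
                [0.15, 0.15, 0.7],   # more European admixed -> ADX1
            ]
        )
        assert name_clusters(means) == ["EUR-like", "ADX2", "ADX1"]

    def test_default_synthetic_run_yields_conventional_names(self):
        c = simulate_cohort(CohortSpec(n_samples=400, n_variants=10, seed=16))
        km = ElbowKMeans(random_state=0).fit(c.q_truth)
        assert sorted(name_clusters(km.cluster_means_)) == [
            "ADX1",
            "ADX2",
            "AFR-like",
            "AME-like",
            "EUR-like",
        ]

    def test_duplicate_claims_suffixed_with_warning(self):
        means = np.array([[0.9, 0.05, 0.05], [0.85, 0.1, 0.05]])
        with pytest.warns(UserWarning, match="AFR-like"):
            names = name_clusters(means)
        assert names == ["AFR-like", "AFR-like.2"]

    def test_cluster_names_invariant_to_component_permutation(self, small_cohort):
        est = AdmixtureEM(mode="supervised", random_state=0).fit(
            small_cohort.matrix, reference_freqs=small_cohort.freqs.freqs
        )
        pops = np.array([""] * small_cohort.matrix.n_samples, dtype=object)
        for k, lab in enumerate(("AFR", "AME", "EUR")):
            pops[np.argsort(-small_cohort.q_truth[:, k])[:8]] = lab
        order = [1, 2, 0]
        Q_aligned, _, _ = align_components(
            est.Q_[:, order], est.components_[order], pops
        )
        km1 = ElbowKMeans(random_state=0).fit(est.Q_)
        km2 = ElbowKMeans(random_state=0).fit(Q_aligned)
        assert sorted(name_clusters(km1.cluster_means_)) == sorted(
            name_clusters(km2.cluster_means_)
        )
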