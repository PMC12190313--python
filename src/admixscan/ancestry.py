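"""Continuous and categorical genetic-ancestry inference.

Three estimators cover the ancestry stage:

* :class:`ReferencePCA` — genotype PCA fitted on a reference panel with
  allele-frequency standardization (mean ``2p``, scale ``sqrt(2p(1-p))``);
  cohort samples are projected onto the reference PC-space.
* :class:`AdmixtureEM` — the K-component admixture model.  Each sample i
  carries a simplex vector ``q_i`` of ancestry fractions and each ancestral
  population k a frequency ``f_kj`` per variant; genotypes are
  Binomial(2, sum_k q_ik f_kj).  The binomial-mixture log-likelihood is
  maximized by EM that allocates each observed allele copy to an ancestry
  of origin, which is provably monotone in the log-likelihood.
* :class:`ElbowKMeans` — K-means over the ancestry fractions with the
  cluster count chosen at the elbow of the SSE curve (maximum second
  difference).

``align_components`` resolves the label-switching ambiguity of
unsupervised fits against a labelled reference panel, and
``name_clusters`` assigns the field's conventional cluster names
(AFR-like / AME-like / EUR-like / ADX1, ADX2, ...).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from .core import GenotypeMatrix, ValidationError

__all__ = [
    "ReferencePCA",
    "AdmixtureEM",
    "ElbowKMeans",
    "align_components",
    "name_clusters",
    "fit_reference_pca",
    "project_samples",
    "admixture_em",
    "kmeans_elbow",
]

_F_EPS = 1e-6


def _as_dosage_array(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return X.dosages
    return np.asarray(X, dtype=float)


class ReferencePCA(BaseEstimator, TransformerMixin):
    """PCA of standardized genotypes, fitted on a reference panel.

    Sites are standardized by mean ``2 p_hat`` and scale
    ``sqrt(2 p_hat (1 - p_hat))`` with ``p_hat`` the reference alternate
    allele frequency; monomorphic sites are dropped.  Residual missing calls
    are mean-imputed (zero after standardization).  ``transform`` projects
    new samples onto the fitted PC-space; reference samples re-project onto
    their own fitted coordinates.

    Parameters
    ----------
    n_components : number of PCs to retain.
    min_overlap : minimum fraction of model sites a projected cohort must
        share when variant ids are supplied.
    """

    def __init__(self, n_components: int = 10, min_overlap: float = 0.5):
        self.n_components = n_components
        self.min_overlap = min_overlap

    def fit(self, X, y=None, variant_ids: list[str] | None = None):
        G = _as_dosage_array(X)
        if isinstance(X, GenotypeMatrix) and variant_ids is None:
            variant_ids = X.variant_ids
        if G.shape[0] < 2:
            raise ValidationError("PCA needs at least 2 reference samples")
        p = np.nanmean(G, axis=0) / 2.0
        keep = (p > 0.0) & (p < 1.0)
        if not keep.any():
            raise ValidationError("all sites monomorphic in the reference panel")
        p = p[keep]
        self.site_mask_ = keep
        self.variant_ids_ = (
            [v for v, k in zip(variant_ids, keep) if k] if variant_ids else None
        )
        self.mean_ = 2.0 * p
        self.scale_ = np.sqrt(2.0 * p * (1.0 - p))
        Z = (G[:, keep] - self.mean_) / self.scale_
        Z[np.isnan(Z)] = 0.0
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        k = min(self.n_components, len(s))
        self.components_ = Vt[:k]
        self.singular_values_ = s[:k]
        with np.errstate(invalid="ignore", divide="ignore"):
            self.percent_variance_ = 100.0 * s**2 / np.sum(s**2)
        self.coordinates_ = U[:, :k] * s[:k]
        return self

    def transform(self, X, variant_ids: list[str] | None = None) -> np.ndarray:
        G = _as_dosage_array(X)
        if isinstance(X, GenotypeMatrix) and variant_ids is None:
            variant_ids = X.variant_ids
        if variant_ids is not None and self.variant_ids_ is not None:
            pos = {v: j for j, v in enumerate(variant_ids)}
            cols = [pos.get(v) for v in self.variant_ids_]
            n_hit = sum(c is not None for c in cols)
            if n_hit < self.min_overlap * len(self.variant_ids_):
                raise ValidationError(
                    f"cohort shares only {n_hit}/{len(self.variant_ids_)} model sites"
                )
            sub = np.full((G.shape[0], len(self.variant_ids_)), np.nan)
            for j, c in enumerate(cols):
                if c is not None:
                    sub[:, j] = G[:, c]
        else:
            if G.shape[1] == self.site_mask_.size:
                sub = G[:, self.site_mask_]
            elif G.shape[1] == int(self.site_mask_.sum()):
                sub = G
            else:
                raise ValidationError("cohort site set inconsistent with the model")
        Z = (sub - self.mean_) / self.scale_
        Z[np.isnan(Z)] = 0.0
        return Z @ self.components_.T


def _em_loop(
    G: np.ndarray,
    Q: np.ndarray,
    F: np.ndarray,
    update_f: bool,
    update_q: bool,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """Allele-allocation EM on the binomial admixture likelihood.

    The E-step attributes each observed alternate (resp. reference) allele
    copy to an ancestry of origin with probability proportional to
    ``q_ik f_kj`` (resp. ``q_ik (1 - f_kj)``); the M-step re-estimates the
    simplex rows of Q and/or the frequency rows of F from the allocated
    copy counts.  Missing genotypes contribute to no sum.
    """
    valid = ~np.isnan(G)
    Galt = np.where(valid, G, 0.0)
    Gref = np.where(valid, 2.0 - G, 0.0)
    m_i = valid.sum(axis=1, keepdims=True).astype(float)
    K = Q.shape[1]
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        S = np.clip(Q @ F, _F_EPS, 1.0 - _F_EPS)
        ll = float(np.sum(Galt * np.log(S) + Gref * np.log1p(-S)))
        if not np.isfinite(ll):
            raise ValidationError("non-finite admixture log-likelihood")
        if trace and ll - trace[-1] < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        Ra = Galt / S
        Rr = Gref / (1.0 - S)
        # expected allele-copy allocations factor into BLAS products:
        # sum_j q_ik f_kj Ra_ij = q_ik (Ra F^T)_ik ; sum_i ... = f_kj (Q^T Ra)_kj
        if update_f:  # uses the E-step allocations of the current Q
            alt_alloc = F * (Q.T @ Ra)
            tot_alloc = alt_alloc + (1.0 - F) * (Q.T @ Rr)
        if update_q:
            q_new = Q * (Ra @ F.T + Rr @ (1.0 - F).T)
            Q = q_new / (2.0 * np.maximum(m_i, 1.0))
            # exact row sums are 1; renormalize to stop float drift compounding
            Q /= Q.sum(axis=1, keepdims=True)
        if update_f:
            with np.errstate(invalid="ignore", divide="ignore"):
                F = np.where(tot_alloc > 0, alt_alloc / tot_alloc, F)
            F = np.clip(F, _F_EPS, 1.0 - _F_EPS)
    return Q, F, trace, converged


class AdmixtureEM(BaseEstimator):
    """Maximum-likelihood admixture proportions by EM.

    Parameters
    ----------
    n_components : number of ancestral populations K (default 3).
    mode : ``"unsupervised"`` jointly estimates ancestry fractions Q and
        ancestral frequencies F; ``"supervised"`` fixes F at the reference
        frequencies passed to :meth:`fit` and estimates Q only.
    tol : stop when the log-likelihood gain per iteration falls below this.
    max_iter : iteration cap; exceeding it sets ``converged_ = False``.
    n_init : random restarts in unsupervised mode (best likelihood kept).
    random_state : seed for initialization.

    Attributes
    ----------
    Q_ : (n_samples, K) ancestry fractions, rows on the simplex.
    components_ : (K, n_variants) ancestral alternate-allele frequencies.
    loglik_trace_ : per-iteration log-likelihood of the kept restart.
    """

    def __init__(
        self,
        n_components: int = 3,
        mode: str = "unsupervised",
        tol: float = 1e-4,
        max_iter: int = 2000,
        n_init: int = 3,
        init_jitter: float = 0.05,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.mode = mode
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.init_jitter = init_jitter
        self.random_state = random_state

    def fit(self, X, y=None, reference_freqs: np.ndarray | None = None):
        G = _as_dosage_array(X)
        K = self.n_components
        if K < 1:
            raise ValidationError("need at least one ancestry component")
        if self.mode not in ("supervised", "unsupervised"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "supervised":
            if reference_freqs is None:
                raise ValidationError("supervised mode requires reference_freqs")
            F0 = np.clip(np.asarray(reference_freqs, float), _F_EPS, 1 - _F_EPS)
            if F0.shape != (K, G.shape[1]):
                raise ValidationError("reference_freqs must be K x n_variants")
        rng = np.random.default_rng(self.random_state)
        site_freq = np.nanmean(G, axis=0) / 2.0
        site_freq = np.nan_to_num(site_freq, nan=0.5)
        best = None
        n_init = self.n_init if self.mode == "unsupervised" else 1
        for _ in range(n_init):
            if self.mode == "supervised":
                # concave per-sample problem: deterministic uniform start
                Q0 = np.full((G.shape[0], K), 1.0 / K)
            else:
                Q0 = rng.dirichlet(np.ones(K), size=G.shape[0])
            if self.mode == "unsupervised":
                F = np.clip(
                    site_freq + rng.uniform(-self.init_jitter, self.init_jitter, (K, G.shape[1])),
                    _F_EPS,
                    1 - _F_EPS,
                )
            else:
                F = F0.copy()
            Q, F, trace, conv = _em_loop(
                G, Q0, F,
                update_f=(self.mode == "unsupervised"),
                update_q=True,
                tol=self.tol,
                max_iter=self.max_iter,
            )
            if best is None or trace[-1] > best[2][-1]:
                best = (Q, F, trace, conv)
        self.Q_, self.components_, self.loglik_trace_, self.converged_ = best
        self.n_iter_ = len(self.loglik_trace_)
        if not self.converged_:
            warnings.warn("admixture EM did not converge within max_iter")
        return self

    def fit_transform(self, X, y=None, **kw) -> np.ndarray:
        return self.fit(X, **kw).Q_


def align_components(
    Q: np.ndarray,
    F: np.ndarray,
    populations: np.ndarray,
    pop_order: tuple[str, ...] = ("AFR", "AME", "EUR"),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permute components so component k matches reference population k.

    ``populations`` holds a population label per sample (empty string or
    None for non-reference cohort samples).  The permutation maximizes the
    summed mean ancestry fraction of each population in its matched
    component (Hungarian assignment); an assignment where some population's
    matched component is not its best component is reported as ambiguous.

    Returns the permuted ``(Q, F)`` and the permutation applied.
    """
    populations = np.asarray(populations, dtype=object)
    means = []
    for pop in pop_order:
        sel = populations == pop
        if not sel.any():
            raise ValidationError(f"no reference samples labelled {pop!r}")
        means.append(Q[sel].mean(axis=0))
    M = np.vstack(means)  # (n_pops, K)
    rows, cols = linear_sum_assignment(-M)
    if any(cols[i] != int(np.argmax(M[i])) for i in range(len(pop_order))):
        raise ValidationError(
            "ambiguous component assignment: two populations favour one component"
        )
    perm = cols
    return Q[:, perm], F[perm, :], perm


class ElbowKMeans(BaseEstimator):
    """K-means over ancestry fractions with elbow selection of the cluster count.

    For every k in ``k_range`` a k-means++ / Lloyd fit (best of ``n_init``
    restarts by SSE) is computed; the chosen count C* maximizes the second
    difference of the SSE curve over interior k — its sharpest bend.  With
    ``criterion="log"`` (default) the curvature is taken on log SSE, which
    is scale-free: the raw-SSE rule is dominated by the first split whenever
    the leading eigendirection carries most variance, while the log rule
    rewards the k past which SSE stops shrinking multiplicatively.
    ``criterion="raw"`` uses the untransformed curve.
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (1, 10),
        n_init: int = 10,
        criterion: str = "log",
        random_state: int | None = None,
    ):
        self.k_range = k_range
        self.n_init = n_init
        self.criterion = criterion
        self.random_state = random_state

    def fit(self, X, y=None):
        Q = np.asarray(X, dtype=float)
        lo, hi = self.k_range
        if Q.shape[0] < hi:
            raise ValidationError(f"need at least {hi} samples for k_range {self.k_range}")
        n_distinct = len(np.unique(Q, axis=0))
        ks, sses, models = [], [], {}
        for k in range(lo, hi + 1):
            if n_distinct < k:
                continue
            km = KMeans(
                n_clusters=k, n_init=self.n_init, random_state=self.random_state
            ).fit(Q)
            ks.append(k)
            sses.append(km.inertia_)
            models[k] = km
        self.k_values_ = np.array(ks)
        self.sse_ = np.array(sses)
        if self.criterion == "log":
            curve = np.log(np.maximum(self.sse_, 1e-12))
        elif self.criterion == "raw":
            curve = self.sse_
        else:
            raise ValidationError(f"unknown elbow criterion {self.criterion!r}")
        if len(ks) < 3:
            best_k = ks[-1]
        else:
            second_diff = curve[:-2] - 2 * curve[1:-1] + curve[2:]
            best_k = ks[1 + int(np.argmax(second_diff))]
        self.n_clusters_ = best_k
        km = models[best_k]
        self.labels_ = km.labels_
        self.cluster_means_ = np.vstack(
            [Q[self.labels_ == c].mean(axis=0) for c in range(best_k)]
        )
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def name_clusters(
    cluster_means: np.ndarray,
    labels: tuple[str, ...] = ("AFR", "AME", "EUR"),
    predominant: float = 0.75,
) -> list[str]:
    """Conventional names for ancestry clusters.

    A cluster whose mean ancestry vector has a component at or above
    ``predominant`` is named ``<component>-like``; the rest are admixed,
    named ADX1, ADX2, ... in order of descending mean European fraction.
    Duplicate "-like" claims get an index suffix with a warning.
    """
    cluster_means = np.asarray(cluster_means, dtype=float)
    if cluster_means.shape[1] != len(labels):
        raise ValidationError("one label per ancestry component required")
    names: dict[int, str] = {}
    used: dict[str, int] = {}
    admixed: list[int] = []
    eur_idx = labels.index("EUR") if "EUR" in labels else cluster_means.shape[1] - 1
    for c, mu in enumerate(cluster_means):
        k = int(np.argmax(mu))
        if mu[k] >= predominant:
            base = f"{labels[k]}-like"
            if base in used:
                used[base] += 1
                warnings.warn(f"multiple clusters claim {base}; suffixing")
                names[c] = f"{base}.{used[base]}"
            else:
                used[base] = 1
                names[c] = base
        else:
            admixed.append(c)
    for rank, c in enumerate(
        sorted(admixed, key=lambda c: -cluster_means[c, eur_idx]), start=1
    ):
        names[c] = f"ADX{rank}"
    return [names[c] for c in range(len(cluster_means))]


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_reference_pca(reference, n_components: int = 10) -> ReferencePCA:
    return ReferencePCA(n_components=n_components).fit(reference)


def project_samples(model: ReferencePCA, cohort) -> np.ndarray:
    return model.transform(cohort)


def admixture_em(
    X,
    K: int = 3,
    mode: str = "unsupervised",
    reference_freqs: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 2000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    est = AdmixtureEM(
        n_components=K, mode=mode, tol=tol, max_iter=max_iter, random_state=seed
    ).fit(X, reference_freqs=reference_freqs)
    return est.Q_, est.components_, est.loglik_trace_


def kmeans_elbow(
    Q, k_range: tuple[int, int] = (1, 10), restarts: int = 10, seed: int | None = None
) -> ElbowKMeans:
    return ElbowKMeans(k_range=k_range, n_init=restarts, random_state=seed).fit(Q)
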