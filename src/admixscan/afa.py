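"""Ancestry-specific allele frequencies from admixed genotypes.

Given individual ancestry fractions Q, the alternate-allele frequency of
each ancestral population at each variant is recovered as the maximum of
the binomial-mixture likelihood

    sum_i [ g_ij log(sum_k q_ik f_kj) + (2 - g_ij) log(1 - sum_k q_ik f_kj) ]

over f_.j in [0,1]^K with Q held fixed — the same allele-allocation EM as
the admixture model, restricted to the frequency updates.  Region-level
allele frequencies are linear projections of the per-ancestry estimates
through region ancestry-composition weights.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ancestry import _em_loop
from .core import ValidationError, GenotypeMatrix

__all__ = ["AncestrySpecificAF", "ancestral_freq_ml", "region_freq"]


class AncestrySpecificAF(BaseEstimator):
    """Per-ancestry allele-frequency MLE with fixed ancestry fractions.

    Parameters
    ----------
    tol, max_iter : EM stopping rule (log-likelihood gain / iteration cap).
    min_mass : components whose total diploid-equivalent ancestry mass
        ``sum_i q_ik`` falls below this are flagged unreliable.

    Attributes
    ----------
    freqs_ : (K, n_variants) estimated alternate-allele frequencies.
    reliable_ : (K,) bool; False where the component mass was too small.
    loglik_trace_ : per-iteration log-likelihood.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 1000, min_mass: float = 1.0):
        self.tol = tol
        self.max_iter = max_iter
        self.min_mass = min_mass

    def fit(self, X, Q: np.ndarray):
        G = X.dosages if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
        Q = np.asarray(Q, dtype=float)
        if Q.shape[0] != G.shape[0]:
            raise ValidationError("Q must cover every sample")
        if Q.shape[1] < 2:
            raise ValidationError("need K >= 2 ancestry components")
        mass = Q.sum(axis=0)
        self.reliable_ = mass >= self.min_mass
        if not self.reliable_.all():
            warnings.warn(
                "ancestry components with negligible total mass; their "
                "frequency estimates are flagged unreliable"
            )
        F0 = np.tile(
            np.clip(np.nan_to_num(np.nanmean(G, axis=0) / 2.0, nan=0.5), 1e-6, 1 - 1e-6),
            (Q.shape[1], 1),
        )
        _, F, trace, _ = _em_loop(
            G, Q, F0, update_f=True, update_q=False, tol=self.tol, max_iter=self.max_iter
        )
        # snap near-boundary estimates produced by the numeric clamp
        F = F.copy()
        F[F <= 2e-6] = 0.0
        F[F >= 1 - 2e-6] = 1.0
        self.freqs_ = F
        self.loglik_trace_ = trace
        return self


def ancestral_freq_ml(
    X, Q: np.ndarray, tol: float = 1e-6, max_iter: int = 1000
) -> np.ndarray:
    """Functional form of :class:`AncestrySpecificAF`; returns the K x m estimates."""
    return AncestrySpecificAF(tol=tol, max_iter=max_iter).fit(X, Q).freqs_


def region_freq(freqs: np.ndarray, weights) -> pd.DataFrame | np.ndarray:
    """Project per-ancestry frequencies to region allele frequencies.

    ``weights`` is either one simplex vector over the K ancestries or a
    DataFrame with columns ``region, w_<anc>...`` (one row per region).
    The estimate for a region is ``sum_k w_k f_k``; the reference-allele
    estimate is its complement.
    """
    freqs = np.asarray(freqs, dtype=float)
    if isinstance(weights, pd.DataFrame):
        wcols = [c for c in weights.columns if c.startswith("w_")]
        rows = []
        for _, r in weights.iterrows():
            w = _check_simplex(r[wcols].to_numpy(dtype=float), freqs.shape[0])
            alt = w @ freqs
            for j, a in enumerate(alt):
                rows.append(
                    {
                        "region": r["region"],
                        "variant_index": j,
                        "alt_freq": a,
                        "ref_freq": 1.0 - a,
                    }
                )
        return pd.DataFrame(rows)
    w = _check_simplex(np.asarray(weights, dtype=float), freqs.shape[0])
    return w @ freqs


def _check_simplex(w: np.ndarray, K: int) -> np.ndarray:
    if w.shape != (K,):
        raise ValidationError(f"weight vector must have length {K}")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValidationError("region weights must be non-negative and sum to 1")
    return w
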