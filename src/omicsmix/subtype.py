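"""Gaussian-mixture subtyping of latent codes.

Full-covariance GMM fitted by EM with k-means++-style seeding, a small
diagonal ridge on every covariance for numerical stability, and best-of-n_init
restarts by final log-likelihood. Hard subtype labels are the maximum
posterior responsibility (ties broken toward the lowest component index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

#: Subtype counts fixed from prior literature for the supported cancer cohorts.
SUBTYPE_K = {
    "OV": 3,
    "CLLE": 6,
    "ESAD": 2,
    "MALY": 3,
    "PACA": 6,
    "RECA": 4,
    "BRCA": 4,
}


@dataclass
class GMMParams:
    K: int
    weights: np.ndarray       # (K,)
    means: np.ndarray         # (K, d)
    covariances: np.ndarray   # (K, d, d)
    log_likelihood_trace: list[float]
    ridge: float = 1e-6


@dataclass
class SubtypeAssignment:
    labels: np.ndarray
    posteriors: np.ndarray
    log_likelihood_trace: list[float]


def choose_k(cancer_code: str) -> int:
    """Subtype count for a supported cancer project code."""
    try:
        return SUBTYPE_K[cancer_code]
    except KeyError:
        raise KeyError(
            f"no established subtype count for {cancer_code!r}; supply K explicitly "
            f"(known codes: {', '.join(sorted(SUBTYPE_K))})"
        ) from None


def _log_gaussian(Z: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = Z.shape[1]
    chol = linalg.cholesky(cov, lower=True)
    solved = linalg.solve_triangular(chol, (Z - mean).T, lower=True)
    maha = np.sum(solved**2, axis=0)
    log_det = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + log_det + maha)


def _log_prob_matrix(params: GMMParams, Z: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [
            np.log(params.weights[k]) + _log_gaussian(Z, params.means[k], params.covariances[k])
            for k in range(params.K)
        ]
    )


def _kmeans_init_means(Z: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Component means from a k-means run (k-means++ seeded), one restart."""
    km = KMeans(
        n_clusters=K, n_init=1, random_state=int(rng.integers(0, 2**31 - 1))
    ).fit(Z)
    return km.cluster_centers_.astype(float)


def _em_once(
    Z: np.ndarray, K: int, rng: np.random.Generator, max_iter: int, tol: float, ridge: float
) -> GMMParams:
    n, d = Z.shape
    means = _kmeans_init_means(Z, K, rng)
    base_cov = np.cov(Z.T, ddof=0).reshape(d, d) + ridge * np.eye(d)
    covs = np.repeat(base_cov[None], K, axis=0)
    weights = np.full(K, 1.0 / K)
    params = GMMParams(K, weights, means, covs, [], ridge)

    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        # E step
        log_prob = _log_prob_matrix(params, Z)
        log_norm = logsumexp(log_prob, axis=1)
        resp = np.exp(log_prob - log_norm[:, None])
        ll = float(log_norm.sum())
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
        # M step
        nk = resp.sum(axis=0) + 1e-12
        params.weights = nk / n
        params.means = (resp.T @ Z) / nk[:, None]
        for k in range(K):
            diff = Z - params.means[k]
            cov = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            params.covariances[k] = cov + ridge * np.eye(d)
    params.log_likelihood_trace = trace
    return params


def gmm_fit(
    Z: np.ndarray,
    K: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 200,
    tol: float = 1e-4,
    ridge: float = 1e-6,
) -> GMMParams:
    """EM fit, best of ``n_init`` seeded initialisations by final log-likelihood."""
    Z = np.asarray(Z, float)
    if not np.isfinite(Z).all():
        raise ValueError("latent matrix contains non-finite values")
    n = Z.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be smaller than the number of samples ({n})")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    best: GMMParams | None = None
    for _ in range(n_init):
        params = _em_once(Z, K, rng, max_iter, tol, ridge)
        if best is None or params.log_likelihood_trace[-1] > best.log_likelihood_trace[-1]:
            best = params
    assert best is not None
    return best


def gmm_posteriors(params: GMMParams, Z: np.ndarray) -> np.ndarray:
    log_prob = _log_prob_matrix(params, np.asarray(Z, float))
    return np.exp(log_prob - logsumexp(log_prob, axis=1)[:, None])


def assign_subtypes(params: GMMParams, Z: np.ndarray) -> SubtypeAssignment:
    post = gmm_posteriors(params, Z)
    labels = post.argmax(axis=1)  # argmax takes the lowest index on ties
    return SubtypeAssignment(labels, post, list(params.log_likelihood_trace))


def pca_project(Z: np.ndarray, d: int = 2) -> np.ndarray:
    """Project latent codes onto the top-d principal axes (deterministic up to sign)."""
    Z = np.asarray(Z, float)
    if d > Z.shape[1]:
        raise ValueError("d cannot exceed the latent dimensionality")
    return PCA(n_components=d, svd_solver="full").fit_transform(Z)
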