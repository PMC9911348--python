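"""Kernels, linear mean functions and sparse variational GP building blocks.

Each spatial component carries a stationary kernel (Matern-3/2 by default,
exponentiated-quadratic as an alternative) with its own amplitude and
lengthscale, a linear mean over the spatial coordinates, and a whitened
inducing-point variational posterior q(u) = N(q_mu, q_sqrt q_sqrt').
Whitening means q parameterizes L^{-1}(u - mu(Z)) where L = chol(K_ZZ),
so the KL against the prior has the simple closed form implemented in
:func:`svgp_kl` and the prior is recovered at q_mu = 0, q_sqrt = I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial.distance import cdist

from .exceptions import InvalidArgumentError, InvalidStateError, NumericalError

JITTER_LADDER = (1e-6, 1e-4, 1e-2)


@dataclass
class KernelSpec:
    """Stationary kernel family with per-component hyperparameters."""

    family: str = "matern32"
    amplitude: float = 1.0
    lengthscale: float = 1.0

    def __post_init__(self):
        if self.family not in ("matern32", "eq"):
            raise InvalidArgumentError(f"unknown kernel family {self.family!r}")
        if self.amplitude <= 0 or self.lengthscale <= 0:
            raise InvalidArgumentError("amplitude and lengthscale must be positive")


@dataclass
class MeanFunction:
    """Linear mean mu(x) = beta0 + x' beta1 over spatial coordinates."""

    beta0: float = 0.0
    beta1: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.beta1 = np.asarray(self.beta1, dtype=float)
        if not (np.isfinite(self.beta0) and np.all(np.isfinite(self.beta1))):
            raise InvalidArgumentError("mean-function coefficients must be finite")


@dataclass
class SVGPState:
    """Whitened variational state of one GP component.

    q_sqrt is a lower-triangular root of the whitened variational
    covariance with strictly positive diagonal.
    """

    Z: np.ndarray
    q_mu: np.ndarray
    q_sqrt: np.ndarray
    jitter: float = 1e-6

    def __post_init__(self):
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.q_mu = np.asarray(self.q_mu, dtype=float)
        self.q_sqrt = np.asarray(self.q_sqrt, dtype=float)
        M = self.Z.shape[0]
        if self.q_mu.shape != (M,) or self.q_sqrt.shape != (M, M):
            raise InvalidStateError("q_mu/q_sqrt shapes inconsistent with Z")
        if np.any(np.triu(self.q_sqrt, 1) != 0):
            raise InvalidStateError("q_sqrt must be lower-triangular")
        if np.any(np.diag(self.q_sqrt) <= 0):
            raise InvalidStateError("q_sqrt diagonal must be positive")


def kernel_matrix(X1, X2, spec: KernelSpec) -> np.ndarray:
    """Cross-covariance matrix under ``spec``.

    matern32: a^2 (1 + sqrt(3) r / l) exp(-sqrt(3) r / l)
    eq:       a^2 exp(-r^2 / (2 l^2))
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise InvalidArgumentError("coordinate dimensions must match")
    r = cdist(X1, X2)
    a2 = spec.amplitude ** 2
    if spec.family == "matern32":
        u = np.sqrt(3.0) * r / spec.lengthscale
        return a2 * (1.0 + u) * np.exp(-u)
    return a2 * np.exp(-(r ** 2) / (2.0 * spec.lengthscale ** 2))


def linear_mean(X, mean: MeanFunction) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != mean.beta1.shape[0]:
        raise InvalidArgumentError(
            f"coordinate dimension {X.shape[1]} does not match beta1 ({mean.beta1.shape[0]})"
        )
    return mean.beta0 + X @ mean.beta1


def chol_with_jitter(K: np.ndarray, ladder=JITTER_LADDER) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of K + jitter*scale*I, escalating jitter on failure."""
    scale = max(float(np.mean(np.diag(K))), 1e-300)
    for jit in ladder:
        try:
            L = cholesky(K + jit * scale * np.eye(K.shape[0]), lower=True)
            return L, jit
        except np.linalg.LinAlgError:
            continue
    raise NumericalError(
        f"Cholesky failed for {K.shape[0]}x{K.shape[0]} kernel matrix "
        f"after jitter ladder {ladder}; condition may be degenerate "
        "(duplicate inducing points or extreme lengthscale)"
    )


def svgp_predict(state: SVGPState, spec: KernelSpec, mean: MeanFunction, Xq):
    """Marginal predictive moments of q(f) = ∫ p(f | u) q(u) du at Xq.

    mean: mu(Xq) + K_qZ L^{-T} q_mu
    var:  k(x,x) - diag(K_qZ K_ZZ^{-1} K_Zq) + rowsumsq(K_qZ L^{-T} q_sqrt)
    Returns (mean_vector, variance_vector); variances strictly positive.
    """
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    Kzz = kernel_matrix(state.Z, state.Z, spec)
    L, _ = chol_with_jitter(Kzz, ladder=(state.jitter,) + JITTER_LADDER)
    Kzq = kernel_matrix(state.Z, Xq, spec)
    C = solve_triangular(L, Kzq, lower=True)            # (M, Nq) = L^{-1} K_Zq
    mu = linear_mean(Xq, mean) + C.T @ state.q_mu
    B = state.q_sqrt.T @ C                              # (M, Nq)
    var = spec.amplitude ** 2 - np.sum(C ** 2, axis=0) + np.sum(B ** 2, axis=0)
    return mu, np.clip(var, 1e-12, None)


def svgp_kl(state: SVGPState) -> float:
    """KL(q(u) || N(0, I)) in the whitened parameterization.

    0.5 * (||q_mu||^2 + ||q_sqrt||_F^2 - M - 2 sum log diag(q_sqrt));
    zero iff q_mu = 0 and q_sqrt = I.
    """
    d = np.diag(state.q_sqrt)
    if np.any(d <= 0):
        raise InvalidStateError("q_sqrt diagonal must be positive")
    M = state.q_mu.shape[0]
    return 0.5 * float(
        state.q_mu @ state.q_mu + np.sum(state.q_sqrt ** 2) - M - 2.0 * np.sum(np.log(d))
    )


def choose_inducing_points(X, M=None, strategy: str = "all", seed: int = 0) -> np.ndarray:
    """Inducing locations: all unique coordinates, k-means centroids, or a random subset."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[0]
    if strategy == "all":
        _, idx = np.unique(X, axis=0, return_index=True)
        return X[np.sort(idx)]
    if M is None:
        raise InvalidArgumentError(f"strategy {strategy!r} requires M")
    if strategy == "random":
        if M > N:
            raise InvalidArgumentError(f"M={M} exceeds N={N}")
        rng = np.random.default_rng(seed)
        return X[np.sort(rng.choice(N, size=M, replace=False))]
    if strategy == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=M, random_state=seed, n_init=4).fit(X)
        return km.cluster_centers_
    raise InvalidArgumentError(f"unknown inducing-point strategy {strategy!r}")


def rescale_coords(X) -> tuple[np.ndarray, float, np.ndarray]:
    """Shift-and-scale coordinates so the longest side of the bounding box is 1.

    Aspect ratio is preserved (a single global scale). Returns
    (X_scaled, scale, offset) with X_scaled = (X - offset) / scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    offset = X.min(axis=0)
    extent = X.max(axis=0) - offset
    scale = float(extent.max())
    if scale <= 0:
        scale = 1.0
    return (X - offset) / scale, scale, offset
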