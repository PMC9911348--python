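"""Initialization, Moran's I ordering, Adam optimization and convergence.

The convergence detector follows a smoothed-trace rule: starting at
iteration 110 and repeating every 10 iterations, a cubic polynomial is
least-squares fitted to the most recent 100 raw objective values; both the
current and the previous check's iteration are evaluated from the current
polynomial, and convergence is declared when the relative change between
those two smoothed values drops below 5e-5. Because the cubic fit is a
linear smoother, rescaling the objective leaves the stopping iteration
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .exceptions import InvalidArgumentError

CONV_START = 110
CONV_WINDOW = 100
CONV_STRIDE = 10
CONV_TOL = 5e-5


@dataclass
class TraceLog:
    """Optimization trace: raw objective values and smoothed checkpoints."""

    iterations: list = field(default_factory=list)
    objective: list = field(default_factory=list)
    smoothed: dict = field(default_factory=dict)  # iteration -> smoothed value
    converged_at: int | None = None

    def append(self, iteration: int, value: float):
        self.iterations.append(iteration)
        self.objective.append(float(value))


# ---------------------------------------------------------------------------
# Initialization

def init_real(Y_tilde: np.ndarray, L: int):
    """Truncated-SVD initialization for real-valued models.

    F0 = U_L S_L, W0 = V_L, so F0 W0' is the best rank-L approximation.
    """
    Y_tilde = np.asarray(Y_tilde, dtype=float)
    if L > min(Y_tilde.shape):
        raise InvalidArgumentError(f"L={L} exceeds min(N, J)={min(Y_tilde.shape)}")
    U, S, Vt = np.linalg.svd(Y_tilde, full_matrices=False)
    return U[:, :L] * S[:L], Vt[:L].T


def init_nonneg(Y, L: int, seed: int = 0, size_factors=None, max_iter: int = 500):
    """NMF initialization for nonnegative models (scikit-learn backend).

    Counts are size-factor adjusted (Y_ij / nu_i) before factorization so
    the initialization targets rates rather than raw counts.
    """
    from sklearn.decomposition import NMF

    Yd = Y.toarray() if sp.issparse(Y) else np.asarray(Y, dtype=float)
    if L > min(Yd.shape):
        raise InvalidArgumentError(f"L={L} exceeds min(N, J)={min(Yd.shape)}")
    if size_factors is not None:
        Yd = Yd / np.asarray(size_factors, dtype=float)[:, None]
    nmf = NMF(
        n_components=L, init="nndsvda", random_state=seed,
        max_iter=max_iter, tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F0 = nmf.fit_transform(Yd)
    return F0, nmf.components_.T


# ---------------------------------------------------------------------------
# Moran's I

def knn_adjacency(X, k: int = 6) -> sp.csr_matrix:
    """Symmetric binary k-nearest-neighbor graph over coordinates."""
    from sklearn.neighbors import NearestNeighbors

    X = np.atleast_2d(np.asarray(X, dtype=float))
    nn = NearestNeighbors(n_neighbors=min(k + 1, X.shape[0])).fit(X)
    A = nn.kneighbors_graph(X, mode="connectivity")
    A.setdiag(0)
    A.eliminate_zeros()
    A = A.maximum(A.T)
    return A.tocsr()


def morans_i(z, adjacency) -> float:
    """Moran's I spatial autocorrelation of z under nonnegative weights.

    I = (N / sum_ij w_ij) * sum_ij w_ij (z_i - zbar)(z_j - zbar)
        / sum_i (z_i - zbar)^2.
    A constant z has undefined I; by convention 0.0 is returned with a
    warning so component sorting remains total.
    """
    z = np.asarray(z, dtype=float)
    N = z.shape[0]
    if N < 2:
        raise InvalidArgumentError("Moran's I requires at least two observations")
    A = adjacency.tocsr() if sp.issparse(adjacency) else sp.csr_matrix(np.asarray(adjacency, dtype=float))
    w_sum = A.sum()
    if w_sum <= 0:
        raise InvalidArgumentError("adjacency has no positive weights")
    d = z - z.mean()
    denom = float(d @ d)
    if denom == 0.0:
        warnings.warn("constant input to Moran's I; returning 0 by convention")
        return 0.0
    num = float(d @ (A @ d))
    return (N / w_sum) * num / denom


def sort_components_by_moran(F0, W0, X, T: int, k: int = 6):
    """Permute components by decreasing Moran's I of the factor columns.

    The first T components after sorting form the spatial block; the
    product F0 W0' is unchanged by the permutation. Returns
    (F0_sorted, W0_sorted, moran_values_sorted).
    """
    F0 = np.asarray(F0, dtype=float)
    W0 = np.asarray(W0, dtype=float)
    if T > F0.shape[1]:
        raise InvalidArgumentError("T cannot exceed the number of components")
    A = knn_adjacency(X, k=k)
    vals = np.array([morans_i(F0[:, l], A) for l in range(F0.shape[1])])
    order = np.argsort(-vals, kind="stable")
    return F0[:, order], W0[:, order], vals[order]


# ---------------------------------------------------------------------------
# Convergence detection

def _smoothed_pair(values: np.ndarray, t: int, stride: int, window: int):
    """Cubic least-squares smoother on the last `window` values ending at t.

    Returns smoothed values at iterations t and t - stride, both evaluated
    from the same polynomial. Iterations are 1-based.
    """
    seg = values[t - window: t]
    x = np.arange(t - window + 1, t + 1, dtype=float)
    # center/scale to [-1, 1] to keep the Vandermonde well conditioned
    mid, half = x.mean(), (x[-1] - x[0]) / 2.0
    xs = (x - mid) / half
    coef = np.polynomial.polynomial.polyfit(xs, seg, 3)
    at = np.polynomial.polynomial.polyval((np.array([t, t - stride]) - mid) / half, coef)
    return float(at[0]), float(at[1])


def check_convergence(
    values,
    start: int = CONV_START,
    window: int = CONV_WINDOW,
    stride: int = CONV_STRIDE,
    tol: float = CONV_TOL,
):
    """First iteration at which the smoothed objective has converged, or None.

    ``values`` holds one raw objective value per iteration (iteration 1 is
    values[0]). Checks run at iterations start, start+stride, ...
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    for t in range(start, n + 1, stride):
        now, prev = _smoothed_pair(values, t, stride, window)
        denom = abs(prev)
        if denom == 0.0:
            if abs(now - prev) == 0.0:
                return t
            continue
        if abs(now - prev) / denom < tol:
            return t
    return None


# ---------------------------------------------------------------------------
# Adam

class Adam:
    """Standard Adam optimizer over a dict of NumPy parameter arrays."""

    def __init__(self, params: dict, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        """In-place gradient-descent step (pass gradients of the loss)."""
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
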