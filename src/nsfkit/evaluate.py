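"""Benchmark metrics for factor-model fits.

Held-out goodness of fit is the mean (over observations) of the
feature-summed Poisson deviance between predicted means and observed
counts; factor/loading recovery is the minimum over true components of
the best absolute Pearson correlation to any fitted component.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import xlogy

from .exceptions import InvalidArgumentError
from .training import knn_adjacency, morans_i


@dataclass
class BenchmarkRecord:
    """One row of a model-comparison table."""

    family: str
    L: int
    T: int
    likelihood: str
    kernel: str | None
    M: int | None
    validation_deviance: float
    validation_rmse: float
    training_deviance: float | None
    sparsity: float
    iterations: int
    converged_at: int | None
    seed: int

    def as_dict(self):
        return asdict(self)


def mean_poisson_deviance(y, mu) -> float:
    """Average over observations of the feature-summed Poisson deviance.

    Per entry d = 2[y log(y/mu) - (y - mu)] with 0 log 0 = 0.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise InvalidArgumentError("y and mu must have equal shapes")
    if np.any(mu <= 0):
        raise InvalidArgumentError("predicted means must be strictly positive")
    d = 2.0 * (xlogy(y, y) - xlogy(y, mu) - (y - mu))
    if d.ndim == 1:
        return float(d.sum())
    return float(d.sum(axis=1).mean())


def rmse(y, pred) -> float:
    """Root mean squared elementwise difference."""
    y = np.asarray(y, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if y.shape != pred.shape:
        raise InvalidArgumentError("shapes must match")
    return float(np.sqrt(np.mean((y - pred) ** 2)))


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 by convention if either input is constant."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def match_factors(F_hat, F_true):
    """Best |Pearson r| per true component, and the minimum over components.

    For each column of F_true, the fitted column of F_hat with the highest
    absolute correlation is identified; the summary is the minimum of
    those maxima. Applies equally to loadings matrices. Returns
    (per_true_best, min_over_true).
    """
    F_hat = np.asarray(F_hat, dtype=float)
    F_true = np.asarray(F_true, dtype=float)
    if F_hat.shape[0] != F_true.shape[0]:
        raise InvalidArgumentError("factor matrices must have equal row counts")
    if F_hat.shape[1] < 1 or F_true.shape[1] < 1:
        raise InvalidArgumentError("need at least one component on each side")
    best = np.array([
        max(abs(_safe_corr(F_true[:, t], F_hat[:, l])) for l in range(F_hat.shape[1]))
        for t in range(F_true.shape[1])
    ])
    return best, float(best.min())


def loadings_sparsity(W, tol: float = 1e-6) -> float:
    """Fraction of loading entries with |w| <= tol * max|W|.

    Exponential-parameterized loadings are never exactly zero, so "zero"
    means negligible relative to the largest entry.
    """
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        raise InvalidArgumentError("empty loadings matrix")
    if tol < 0:
        raise InvalidArgumentError("tol must be nonnegative")
    thresh = tol * np.abs(W).max()
    return float(np.mean(np.abs(W) <= thresh))


def score_recovery_distance(scores_hat, scores_true) -> float:
    """Euclidean distance between fitted and true spatial-importance scores."""
    a = np.asarray(scores_hat, dtype=float)
    b = np.asarray(scores_true, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("score vectors must have equal length")
    return float(np.linalg.norm(a - b))


def factor_morans_i(F, X, k: int = 6) -> np.ndarray:
    """Moran's I of each factor column under the pinned k-NN adjacency."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    A = knn_adjacency(X, k=k)
    import warnings as _w

    vals = []
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        for l in range(F.shape[1]):
            vals.append(morans_i(F[:, l], A))
    return np.array(vals)


def benchmark_fit(results, dataset, train_idx, val_idx, seed: int = 0) -> BenchmarkRecord:
    """Evaluate one fitted model on a held-out split of a CountDataset.

    Count models are scored against held-out counts using predicted means
    at the held-out coordinates; Gaussian models have their normalized
    predictions inverted back to the count scale first.
    """
    from .preprocess import invert_lognormalize, lognormalize_center

    m = results.model
    Y = dataset.counts()
    Yv = Y[val_idx]
    if m.likelihood == "gau":
        norm = lognormalize_center(Y[train_idx])
        pred_tilde = results.predict_mean(dataset.X[val_idx])
        totals_v = Yv.sum(axis=1)
        mu = invert_lognormalize(pred_tilde, norm, totals=totals_v)
        ytilde_v = np.log1p(Yv * (norm.median_total / totals_v)[:, None]) - norm.centering_means
        val_rmse = rmse(ytilde_v, pred_tilde)
        train_dev = None
    else:
        mu = results.predict_mean(dataset.X[val_idx], size_factors=dataset.nu[val_idx])
        val_rmse = rmse(Yv, mu)
        train_dev = mean_poisson_deviance(Y[train_idx], results.predict_mean())
    val_dev = mean_poisson_deviance(Yv, np.clip(mu, 1e-12, None))
    des = m._design or {}
    return BenchmarkRecord(
        family=m.family, L=m.L, T=m.T, likelihood=m.likelihood,
        kernel=des["spec"].family if m.spatial else None,
        M=des.get("M"), validation_deviance=val_dev, validation_rmse=val_rmse,
        training_deviance=train_dev,
        sparsity=loadings_sparsity(results.loadings),
        iterations=len(results.trace.objective),
        converged_at=results.trace.converged_at, seed=seed,
    )
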