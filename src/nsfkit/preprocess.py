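"""Feature selection, size factors, normalization and data splitting.

Count models (PNMF, NSF, NSFH) consume raw counts plus size factors;
Gaussian-likelihood models (FA, RSF) consume a median-ratio normalized,
log1p-transformed and feature-centered matrix. Informative features are
ranked by Poisson deviance against a size-factor-adjusted constant null.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import xlogy

from .containers import NormalizedDataset
from .exceptions import InvalidArgumentError


def _dense(Y) -> np.ndarray:
    return Y.toarray() if sp.issparse(Y) else np.asarray(Y, dtype=float)


def _row_totals(Y) -> np.ndarray:
    Yd = _dense(Y)
    totals = Yd.sum(axis=1)
    bad = np.where(totals <= 0)[0]
    if bad.size:
        raise InvalidArgumentError(
            f"observation rows with zero total counts: {bad[:10].tolist()}"
        )
    return totals


def compute_size_factors(Y) -> np.ndarray:
    """Size factors nu_i = (row total)_i / median(row totals); median(nu) = 1."""
    totals = _row_totals(Y)
    return totals / np.median(totals)


def poisson_deviance_per_gene(Y, size_factors=None) -> np.ndarray:
    """Per-gene Poisson deviance against the null y_hat_ij = nu_i * sum_i(y_j)/sum_i(nu).

    The null is the best constant-rate fit given the size factors; a gene
    whose counts are exactly proportional to nu has deviance 0.
    """
    Yd = _dense(Y)
    if size_factors is None:
        size_factors = compute_size_factors(Yd)
    nu = np.asarray(size_factors, dtype=float)
    rate = Yd.sum(axis=0) / nu.sum()          # (J,)
    yhat = np.outer(nu, rate)                  # (N, J)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = xlogy(Yd, Yd) - xlogy(Yd, yhat)
    dev = 2.0 * (term - (Yd - yhat))
    return dev.sum(axis=0)


def select_informative_genes(Y, n_top: int = 2000, size_factors=None) -> np.ndarray:
    """Indices of the n_top genes with largest Poisson deviance, descending."""
    J = Y.shape[1]
    if n_top > J:
        raise InvalidArgumentError(f"n_top={n_top} exceeds feature count J={J}")
    dev = poisson_deviance_per_gene(Y, size_factors)
    order = np.argsort(-dev, kind="stable")
    return order[:n_top]


def lognormalize_center(Y) -> NormalizedDataset:
    """Median-total normalization, log1p transform, per-feature centering."""
    Yd = _dense(Y)
    totals = _row_totals(Yd)
    med = float(np.median(totals))
    scaled = Yd * (med / totals)[:, None]
    logged = np.log1p(scaled)
    means = logged.mean(axis=0)
    return NormalizedDataset(
        Y_tilde=logged - means, centering_means=means, median_total=med, totals=totals
    )


def invert_lognormalize(Y_tilde_pred, norm: NormalizedDataset, totals=None) -> np.ndarray:
    """Map Gaussian-model predictions back to the count scale.

    Adds the centering means, inverts log1p, and rescales each row by
    total/median_total. ``totals`` defaults to the training totals stored
    in ``norm``; pass held-out totals when predicting validation counts.
    Results are clipped below at 1e-8 so count-scale deviances are defined.
    """
    if totals is None:
        totals = norm.totals
    totals = np.asarray(totals, dtype=float)
    raw = np.expm1(Y_tilde_pred + norm.centering_means)
    raw = raw * (totals / norm.median_total)[:, None]
    return np.clip(raw, 1e-8, None)


def split_train_validation(N: int, frac: float = 0.05, seed: int = 0):
    """Random disjoint, exhaustive train/validation index split.

    Validation size is round(frac * N) with banker's rounding for
    cross-platform reproducibility. Returns (train_idx, val_idx), each
    sorted ascending.
    """
    if not 0 < frac < 1:
        raise InvalidArgumentError("frac must lie strictly between 0 and 1")
    n_val = round(frac * N)
    if n_val == 0 or n_val == N:
        raise InvalidArgumentError(
            f"degenerate split: frac={frac} with N={N} gives {n_val} validation rows"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    val = np.sort(perm[:n_val])
    train = np.sort(perm[n_val:])
    return train, val
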