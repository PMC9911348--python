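"""Simplex projection of nonnegative factorizations and spatial scores.

The likelihood of a nonnegative factorization depends on F, W only through
Lambda = F W', so any rescaling that preserves the product is admissible.
Two normalizations are provided:

* SPDE-style: columns of F sum to one, rows of W sum to one; a per-feature
  scale vector w_bar carries the remaining mass
  (Lambda = F W' diag(w_bar)). Rows of W then read as a feature's soft
  assignment over components.
* LDA-style: the roles are switched — columns of W sum to one ("topics"),
  rows of F sum to one, and a per-observation scale vector carries the
  mass (Lambda = diag(scale) F W').

For a hybrid factorization with spatial blocks [F, H] / [W, V], the spatial
importance score of feature j is the summed spatial share of its projected
loadings (gamma_j, SPDE-style) and of observation i the summed spatial
share of its projected factors (rho_i, LDA-style); both lie in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError

_ZERO_TOL = 1e-12


@dataclass
class SimplexFactorization:
    """Simplex-normalized (F, W) with the scale vector restoring Lambda."""

    F: np.ndarray
    W: np.ndarray
    scale: np.ndarray  # per-feature (spde) or per-observation (lda)
    style: str

    @property
    def w_bar(self) -> np.ndarray:
        return self.scale

    def reconstruct(self) -> np.ndarray:
        """Lambda recovered from the normalized blocks."""
        if self.style == "spde":
            return self.F @ (self.W * self.scale[:, None]).T
        return self.scale[:, None] * (self.F @ self.W.T)


def _check_nonneg(F, W):
    F = np.asarray(F, dtype=float)
    W = np.asarray(W, dtype=float)
    if F.ndim != 2 or W.ndim != 2 or F.shape[1] != W.shape[1]:
        raise InvalidArgumentError("F (N x L) and W (J x L) must share L columns")
    if F.min() < 0 or W.min() < 0:
        raise InvalidArgumentError("simplex projection requires nonnegative inputs")
    return F, W


def project_simplex_spde(F, W) -> SimplexFactorization:
    """Column-normalize F, row-normalize W, keeping F W' diag(w_bar) invariant."""
    F, W = _check_nonneg(F, W)
    fbar = F.sum(axis=0)
    bad = np.where(fbar <= _ZERO_TOL)[0]
    if bad.size:
        raise InvalidArgumentError(f"all-zero factor column(s): {bad.tolist()}")
    Fn = F / fbar
    Ws = W * fbar
    wbar = Ws.sum(axis=1)
    badr = np.where(wbar <= _ZERO_TOL)[0]
    if badr.size:
        raise InvalidArgumentError(f"all-zero loading row(s): {badr[:10].tolist()}")
    Wn = Ws / wbar[:, None]
    return SimplexFactorization(F=Fn, W=Wn, scale=wbar, style="spde")


def project_simplex_lda(F, W) -> SimplexFactorization:
    """Column-normalize W ('topics'), row-normalize F; per-observation scale."""
    F, W = _check_nonneg(F, W)
    wbar = W.sum(axis=0)
    bad = np.where(wbar <= _ZERO_TOL)[0]
    if bad.size:
        raise InvalidArgumentError(f"all-zero loading column(s): {bad.tolist()}")
    Wn = W / wbar
    Fs = F * wbar
    fbar = Fs.sum(axis=1)
    badr = np.where(fbar <= _ZERO_TOL)[0]
    if badr.size:
        raise InvalidArgumentError(f"all-zero factor row(s): {badr[:10].tolist()}")
    Fn = Fs / fbar[:, None]
    return SimplexFactorization(F=Fn, W=Wn, scale=fbar, style="lda")


def gene_spatial_scores(W_spatial, V_nonspatial, F, H) -> np.ndarray:
    """Per-feature spatial importance gamma_j in [0, 1].

    SPDE-style projection of the concatenated blocks A = [F, H],
    B = [W, V], then gamma_j = sum of the first T projected loadings.
    T = 0 gives all zeros; T = L gives all ones.
    """
    W_spatial = np.asarray(W_spatial, dtype=float)
    V_nonspatial = np.asarray(V_nonspatial, dtype=float)
    T = W_spatial.shape[1] if W_spatial.ndim == 2 else 0
    K = V_nonspatial.shape[1] if V_nonspatial.ndim == 2 else 0
    J = W_spatial.shape[0] if T else V_nonspatial.shape[0]
    if T == 0:
        return np.zeros(J)
    if K == 0:
        return np.ones(J)
    A = np.hstack([np.asarray(F, dtype=float), np.asarray(H, dtype=float)])
    B = np.hstack([W_spatial, V_nonspatial])
    proj = project_simplex_spde(A, B)
    return np.clip(proj.W[:, :T].sum(axis=1), 0.0, 1.0)


def observation_spatial_scores(F, H, W, V) -> np.ndarray:
    """Per-observation spatial importance rho_i in [0, 1] (LDA-style)."""
    F = np.asarray(F, dtype=float)
    H = np.asarray(H, dtype=float)
    T = F.shape[1] if F.ndim == 2 else 0
    K = H.shape[1] if H.ndim == 2 else 0
    N = F.shape[0] if T else H.shape[0]
    if T == 0:
        return np.zeros(N)
    if K == 0:
        return np.ones(N)
    A = np.hstack([F, H])
    B = np.hstack([np.asarray(W, dtype=float), np.asarray(V, dtype=float)])
    proj = project_simplex_lda(A, B)
    return np.clip(proj.F[:, :T].sum(axis=1), 0.0, 1.0)


def top_genes(W, component: int, k: int = 5, feature_ids=None) -> np.ndarray:
    """The k features with largest loading on a component, descending.

    Ties break toward the smaller feature index. If feature_ids is given,
    returns labels; otherwise integer indices. k > J truncates with a
    warning.
    """
    W = np.asarray(W, dtype=float)
    J = W.shape[0]
    if not 0 <= component < W.shape[1]:
        raise InvalidArgumentError(f"component {component} out of range")
    if k > J:
        warnings.warn(f"k={k} exceeds feature count {J}; truncating")
        k = J
    order = np.argsort(-W[:, component], kind="stable")[:k]
    if feature_ids is not None:
        return np.asarray(feature_ids)[order]
    return order
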