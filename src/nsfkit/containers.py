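"""In-memory containers for spatial count data and simulation ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .exceptions import InvalidArgumentError


def _to_dense(Y):
    return Y.toarray() if sp.issparse(Y) else np.asarray(Y)


@dataclass
class CountDataset:
    """A counts matrix with aligned spatial coordinates.

    Attributes
    ----------
    Y : (N, J) array or sparse matrix
        Nonnegative integer counts, observations in rows.
    X : (N, D) array
        Spatial coordinates, one row per observation. Duplicate rows are
        allowed (several cells can share a location).
    nu : (N,) array
        Positive per-observation size factors. Defaults to all ones.
    feature_ids : (J,) sequence of str
    train_mask : optional (N,) bool array; True marks training rows.
    """

    Y: object
    X: np.ndarray
    nu: np.ndarray | None = None
    feature_ids: np.ndarray | None = None
    train_mask: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        N = self.Y.shape[0]
        if self.X.ndim != 2 or self.X.shape[0] != N:
            raise InvalidArgumentError(
                f"coordinate rows ({self.X.shape[0]}) must align with counts rows ({N})"
            )
        if self.nu is None:
            self.nu = np.ones(N)
        self.nu = np.asarray(self.nu, dtype=float)
        if self.nu.shape != (N,) or np.any(self.nu <= 0):
            raise InvalidArgumentError("size factors must be positive, one per observation")
        if self.feature_ids is None:
            self.feature_ids = np.array([f"feature{j}" for j in range(self.Y.shape[1])])
        else:
            self.feature_ids = np.asarray(self.feature_ids)
        Yd = _to_dense(self.Y)
        if Yd.size and Yd.min() < 0:
            raise InvalidArgumentError("counts must be nonnegative")

    @property
    def n_obs(self) -> int:
        return self.Y.shape[0]

    @property
    def n_features(self) -> int:
        return self.Y.shape[1]

    def counts(self) -> np.ndarray:
        """Dense counts matrix."""
        return _to_dense(self.Y)

    def subset(self, idx: np.ndarray) -> "CountDataset":
        """Row-subset of the dataset (counts, coordinates, size factors)."""
        return CountDataset(
            Y=self.counts()[idx],
            X=self.X[idx],
            nu=self.nu[idx],
            feature_ids=self.feature_ids,
        )


@dataclass
class NormalizedDataset:
    """Median-ratio normalized, log1p-transformed, feature-centered matrix."""

    Y_tilde: np.ndarray
    centering_means: np.ndarray
    median_total: float = 1.0
    totals: np.ndarray | None = None


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic spatial count dataset.

    mean_matrix = 0.2 + F W' (+ H V'), entries >= 0.2 everywhere.
    """

    F: np.ndarray
    H: np.ndarray
    W: np.ndarray
    V: np.ndarray
    mean_matrix: np.ndarray
    true_gene_scores: np.ndarray
    coords: np.ndarray
    seed: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def n_spatial(self) -> int:
        return self.F.shape[1]

    @property
    def n_nonspatial(self) -> int:
        return 0 if self.H.size == 0 else self.H.shape[1]
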