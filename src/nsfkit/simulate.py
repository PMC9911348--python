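"""Synthetic spatial count data with known ground-truth factorizations.

Two pattern libraries on a square grid (36x36 by default) provide binary
spatial factors: ``ggblocks`` (four disjoint shapes, one per quadrant, in
the spirit of the classic Indian-buffet-process image motifs) and ``quilt``
(four axis-aligned patches that overlap in space). Each pattern covers
roughly 20% of the grid, matching the Bernoulli(0.2) activity rate of the
nonspatial factors so that spatial and nonspatial components contribute
comparable mass.

Scenario I draws counts with mean 0.2 + F W' where each feature loads
one-hot (weight 20) on a single spatial pattern; active-region means are
therefore exactly 20.2 and background 0.2. Scenario II adds binary
nonspatial factors H ~ Bernoulli(0.2) with loadings V, mean
0.2 + F W' + H V'; features are either split (half purely spatial with
weight 20, half purely nonspatial with weight 20) or mixed (every feature
has one spatial weight of 12 and one nonspatial weight of 8). Counts are
negative binomial with shape 10 (Var = mu + mu^2/10).

RNG stream order (one generator per dataset, keyed by seed):
scenario I: (1) feature-to-pattern assignment, (2) counts.
scenario II: (1) nonspatial factor draws H, (2) loading assignments
(spatial then nonspatial), (3) counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CountDataset, SimulationTruth
from .exceptions import InvalidArgumentError

# Pattern geometry, in units of 1/36 of the grid side. Versioned constant:
# changing these shapes changes every simulated dataset.
PATTERN_VERSION = 1

_GGBLOCKS_RECTS = {
    # each shape lives in its own quadrant -> pairwise disjoint columns
    "block": [(1, 17, 1, 17)],                      # 16x16 square, top-left
    "hbar": [(2, 16, 18, 36)],                      # horizontal bar, top-right
    "vbar": [(18, 36, 2, 16)],                      # vertical bar, bottom-left
    "cross": [(22, 32, 18, 36), (18, 36, 22, 32)],  # plus sign, bottom-right
}

_QUILT_RECTS = {
    "top_band": [(0, 8, 0, 36)],
    "left_band": [(0, 36, 0, 8)],
    "center_square": [(10, 26, 10, 26)],
    "corner_patch": [(22, 36, 18, 36)],
}


@dataclass
class PatternLibrary:
    """A named set of binary spatial factor patterns on a square grid."""

    name: str
    grid_side: int
    factors: np.ndarray  # (grid_side**2, n_patterns), entries in {0, 1}

    @property
    def n_patterns(self) -> int:
        return self.factors.shape[1]

    def as_images(self) -> np.ndarray:
        """Patterns reshaped to (n_patterns, grid_side, grid_side)."""
        s = self.grid_side
        return self.factors.T.reshape(self.n_patterns, s, s)


def make_grid_coords(grid_side: int) -> np.ndarray:
    """All integer lattice points of a grid_side x grid_side grid, row-major."""
    if grid_side < 2:
        raise InvalidArgumentError("grid_side must be >= 2")
    r, c = np.meshgrid(np.arange(grid_side), np.arange(grid_side), indexing="ij")
    return np.column_stack([r.ravel(), c.ravel()]).astype(float)


def _rects_to_column(rects, grid_side: int) -> np.ndarray:
    img = np.zeros((grid_side, grid_side), dtype=int)
    for (r0, r1, c0, c1) in rects:
        sl = [round(v * grid_side / 36) for v in (r0, r1, c0, c1)]
        img[sl[0]: sl[1], sl[2]: sl[3]] = 1
    return img.ravel()


def pattern_library(name: str, grid_side: int = 36) -> PatternLibrary:
    """Deterministic binary pattern library: ggblocks, quilt, or both."""
    if grid_side < 2:
        raise InvalidArgumentError("grid_side must be >= 2")
    if name == "both":
        gg = pattern_library("ggblocks", grid_side)
        qu = pattern_library("quilt", grid_side)
        return PatternLibrary(name, grid_side, np.hstack([gg.factors, qu.factors]))
    if name == "ggblocks":
        rects = _GGBLOCKS_RECTS
    elif name == "quilt":
        rects = _QUILT_RECTS
    else:
        raise InvalidArgumentError(f"unknown pattern library {name!r}")
    cols = [_rects_to_column(r, grid_side) for r in rects.values()]
    F = np.column_stack(cols)
    if np.any(F.sum(axis=0) == 0):
        raise InvalidArgumentError(
            f"grid_side={grid_side} too small to render the {name} patterns"
        )
    return PatternLibrary(name, grid_side, F)


def draw_negative_binomial(mean, shape: float, seed=None) -> np.ndarray:
    """Negative binomial draws with E = mean and Var = mean + mean**2/shape.

    Implemented as a gamma-Poisson mixture: lambda ~ Gamma(shape, mean/shape),
    y ~ Poisson(lambda). In the textbook (r, p) parameterization this is
    r = shape and p = shape / (shape + mean).
    """
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise InvalidArgumentError("all means must be positive")
    if not np.isscalar(shape) or shape <= 0:
        raise InvalidArgumentError("shape must be a positive scalar")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def _finish_dataset(F, H, W, V, coords, shape, rng, seed):
    from .postprocess import gene_spatial_scores

    mean = 0.2 + F @ W.T
    if H.size:
        mean = mean + H @ V.T
    Y = draw_negative_binomial(mean, shape, rng)
    scores = gene_spatial_scores(W, V, F, H)
    truth = SimulationTruth(
        F=F, H=H, W=W, V=V, mean_matrix=mean,
        true_gene_scores=scores, coords=coords, seed=seed,
    )
    data = CountDataset(Y=Y, X=coords.copy())
    return data, truth


def simulate_scenario1(
    pattern: str,
    n_features: int = 200,
    seed: int = 0,
    grid_side: int = 36,
    shape: float = 10.0,
):
    """Purely spatial scenario: mean 0.2 + F W', one-hot loadings of 20.

    Returns (CountDataset, SimulationTruth).
    """
    if n_features < 1:
        raise InvalidArgumentError("n_features must be >= 1")
    lib = pattern_library(pattern, grid_side)
    F = lib.factors.astype(float)
    coords = make_grid_coords(grid_side)
    T = lib.n_patterns
    rng = np.random.default_rng(seed)
    assign = rng.integers(T, size=n_features)
    W = np.zeros((n_features, T))
    W[np.arange(n_features), assign] = 20.0
    H = np.zeros((F.shape[0], 0))
    V = np.zeros((n_features, 0))
    data, truth = _finish_dataset(F, H, W, V, coords, shape, rng, seed)
    truth.extras["assignment"] = assign
    return data, truth


def simulate_scenario2(
    pattern: str,
    loading_mode: str = "split",
    n_features: int = 500,
    seed: int = 0,
    grid_side: int = 36,
    shape: float = 10.0,
    bernoulli_p: float = 0.2,
):
    """Spatial + nonspatial scenario.

    Nonspatial factor count is 3 for four-pattern libraries and 6 for
    ``both``. split: first half of features one-hot (20) on a spatial
    component, second half one-hot (20) on a nonspatial component. mixed:
    every feature carries one spatial weight of 12 and one nonspatial
    weight of 8. Returns (CountDataset, SimulationTruth).
    """
    if loading_mode not in ("split", "mixed"):
        raise InvalidArgumentError("loading_mode must be 'split' or 'mixed'")
    if n_features < 1:
        raise InvalidArgumentError("n_features must be >= 1")
    if loading_mode == "split" and n_features % 2:
        raise InvalidArgumentError("split mode requires an even n_features")
    lib = pattern_library(pattern, grid_side)
    F = lib.factors.astype(float)
    N, T = F.shape
    K = 6 if lib.n_patterns == 8 else 3
    coords = make_grid_coords(grid_side)
    rng = np.random.default_rng(seed)
    H = rng.binomial(1, bernoulli_p, size=(N, K)).astype(float)
    W = np.zeros((n_features, T))
    V = np.zeros((n_features, K))
    if loading_mode == "split":
        half = n_features // 2
        sp_assign = rng.integers(T, size=half)
        ns_assign = rng.integers(K, size=n_features - half)
        W[np.arange(half), sp_assign] = 20.0
        V[np.arange(half, n_features), ns_assign] = 20.0
    else:
        sp_assign = rng.integers(T, size=n_features)
        ns_assign = rng.integers(K, size=n_features)
        W[np.arange(n_features), sp_assign] = 12.0
        V[np.arange(n_features), ns_assign] = 8.0
    return _finish_dataset(F, H, W, V, coords, shape, rng, seed)
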