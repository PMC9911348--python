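"""Generative factor models for spatial count data and their inference.

Five families share one low-rank structure for the per-observation,
per-feature mean:

* FA    — Gaussian likelihood, real-valued nonspatial factors.
* PNMF  — count likelihood, nonnegative loadings, nonspatial log-factors.
* RSF   — Gaussian likelihood, real-valued factors with GP priors over space.
* NSF   — count likelihood, nonnegative loadings, spatial GP log-factors:
          lambda_ij = sum_l w_jl exp(f_il), y_ij ~ Poi(nu_i lambda_ij).
* NSFH  — hybrid: T spatial and L-T nonspatial components,
          lambda_ij = sum_{l<=T} w_jl exp(f_il) + sum_{l>T} v_jl exp(h_il).

NSFH reduces exactly to NSF at T = L and to PNMF at T = 0. Likelihoods are
modular: Poisson, negative binomial (per-feature shape theta_j) or Gaussian
(per-feature variance sigma_j^2).

Inference maximizes a Monte-Carlo evidence lower bound with reparameterized
draws of the latent factors. Spatial components use whitened inducing-point
variational posteriors (see :mod:`nsfkit.gp_core`); during optimization the
whitened covariance root is diagonal for scalability. Nonnegative loadings
are parameterized as exponentials of unconstrained reals, so they remain
strictly positive throughout optimization. Gradients are analytic and the
optimizer is Adam; the smoothed-trace rule in :mod:`nsfkit.training` stops
the loop.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma, gammaln, xlogy

from . import gp_core, training
from .containers import CountDataset
from .exceptions import InvalidArgumentError, InvalidStateError

FAMILIES = ("fa", "pnmf", "rsf", "nsf", "nsfh")
_REAL = ("fa", "rsf")
_COUNT_LIKS = ("poi", "nb")


@dataclass
class FitConfig:
    """Optimization settings. Defaults are package choices, recorded here."""

    n_samples_elbo: int = 3
    batch_size: int | None = None  # None: full batch for N <= 3000, else 1000
    learning_rate: float = 0.01
    max_iter: int = 1000
    seed: int = 0
    kernel_family: str = "matern32"
    lengthscale: float | None = None  # None: 0.1 of the rescaled domain
    M: int | None = None
    ip_strategy: str = "all"
    jitter: float = 1e-6
    conv_start: int = training.CONV_START
    conv_window: int = training.CONV_WINDOW
    conv_stride: int = training.CONV_STRIDE
    conv_tol: float = training.CONV_TOL

    def __post_init__(self):
        if self.n_samples_elbo < 1 or self.max_iter < 1:
            raise InvalidArgumentError("n_samples_elbo and max_iter must be positive")
        if self.learning_rate <= 0:
            raise InvalidArgumentError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# Spec-level operations


def rate_matrix(W, V, F_draw, H_draw, nu) -> np.ndarray:
    """Poisson intensity nu_i * lambda_ij for nonnegative families.

    lambda_ij = sum_l w_jl exp(f_il) + sum_l v_jl exp(h_il). ``F_draw`` and
    ``H_draw`` are real-valued log-factors; either block may be empty
    (T = L gives the NSF rate, T = 0 the PNMF rate).
    """
    W = np.asarray(W, dtype=float)
    V = np.asarray(V, dtype=float)
    F_draw = np.asarray(F_draw, dtype=float)
    H_draw = np.asarray(H_draw, dtype=float)
    if (W.size and W.min() < 0) or (V.size and V.min() < 0):
        raise InvalidStateError("loadings must be nonnegative")
    nu = np.asarray(nu, dtype=float)
    N = F_draw.shape[0] if F_draw.size else H_draw.shape[0]
    J = W.shape[0] if W.size else V.shape[0]
    lam = np.zeros((N, J))
    if W.size:
        lam += np.exp(F_draw) @ W.T
    if V.size:
        lam += np.exp(H_draw) @ V.T
    return nu[:, None] * lam


def log_likelihood(y, mu, likelihood: str, sigma2=None, theta=None) -> np.ndarray:
    """Per-entry log density of the data under the given likelihood.

    Poisson(mu); NB with mean mu and shape theta (Var = mu + mu^2/theta);
    Gaussian with mean mu and per-feature variance sigma2.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if likelihood in _COUNT_LIKS and np.any(mu <= 0):
        raise InvalidStateError("count likelihoods require strictly positive means")
    if likelihood == "poi":
        return xlogy(y, mu) - mu - gammaln(y + 1.0)
    if likelihood == "nb":
        th = np.broadcast_to(np.asarray(theta, dtype=float), mu.shape[-1:])
        if np.any(th <= 0):
            raise InvalidStateError("negative binomial shape must be positive")
        return (
            gammaln(y + th) - gammaln(th) - gammaln(y + 1.0)
            + th * np.log(th / (th + mu)) + xlogy(y, mu / (th + mu))
        )
    if likelihood == "gau":
        s2 = np.broadcast_to(np.asarray(sigma2, dtype=float), mu.shape[-1:])
        if np.any(s2 <= 0):
            raise InvalidStateError("Gaussian variances must be positive")
        return -0.5 * np.log(2.0 * np.pi * s2) - (y - mu) ** 2 / (2.0 * s2)
    raise InvalidArgumentError(f"unknown likelihood {likelihood!r}")


# ---------------------------------------------------------------------------
# Model


class SpatialFactorModel:
    """Latent factor model for a counts (or normalized) matrix over space.

    Parameters
    ----------
    Y : (N, J) matrix
        Raw counts for count likelihoods; the normalized, centered matrix
        for Gaussian families (see :func:`nsfkit.preprocess.lognormalize_center`).
    coords : (N, D) array, required for spatial families (rsf, nsf, nsfh).
    family : one of 'fa', 'pnmf', 'rsf', 'nsf', 'nsfh'.
    L : total number of components.
    T : number of spatial components (only meaningful for 'nsfh';
        defaults to L // 2 there).
    likelihood : 'poi' (default for nonnegative count families), 'nb',
        or 'gau' (forced for fa/rsf).
    size_factors : (N,) positive array, defaults to ones.
    """

    def __init__(self, Y, coords=None, family: str = "nsf", L: int = 4, T=None,
                 likelihood=None, size_factors=None, feature_ids=None):
        if family not in FAMILIES:
            raise InvalidArgumentError(f"unknown family {family!r}")
        self.family = family
        self.L = int(L)
        if family == "fa" or family == "pnmf":
            self.T = 0
        elif family in ("rsf", "nsf"):
            self.T = self.L
        else:
            self.T = self.L // 2 if T is None else int(T)
            # T = 0 and T = L are admitted as degenerate hybrids; they
            # reduce exactly to PNMF and NSF respectively.
            if not 0 <= self.T <= self.L:
                raise InvalidArgumentError("nsfh requires 0 <= T <= L")
        self.K = self.L - self.T
        self.nonneg = family not in _REAL
        if likelihood is None:
            likelihood = "gau" if family in _REAL else "poi"
        if family in _REAL and likelihood != "gau":
            raise InvalidArgumentError(f"{family} requires the Gaussian likelihood")
        if family not in _REAL and likelihood not in _COUNT_LIKS:
            raise InvalidArgumentError(f"{family} requires a count likelihood (poi/nb)")
        self.likelihood = likelihood

        self.Y = Y.toarray() if sp.issparse(Y) else np.asarray(Y, dtype=float)
        self.N, self.J = self.Y.shape
        self.nu = (np.ones(self.N) if size_factors is None
                   else np.asarray(size_factors, dtype=float))
        if np.any(self.nu <= 0):
            raise InvalidArgumentError("size factors must be positive")
        self.spatial = self.T > 0
        if self.spatial:
            if coords is None:
                raise InvalidArgumentError(f"family {family!r} requires coordinates")
            coords = np.atleast_2d(np.asarray(coords, dtype=float))
            if coords.shape[0] != self.N:
                raise InvalidArgumentError("coordinates must align with Y rows")
        self.coords = coords
        self.feature_ids = (np.asarray(feature_ids) if feature_ids is not None
                            else np.array([f"feature{j}" for j in range(self.J)]))
        self._design = None
        self._params = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dataset(cls, dataset: CountDataset, family: str = "nsf", L: int = 4,
                     T=None, likelihood=None, use_size_factors: bool = False):
        """Build a model from a :class:`CountDataset`.

        Gaussian families get the log-normalized centered matrix; count
        families get raw counts. With ``use_size_factors`` the scanpy-style
        median-ratio size factors are attached (off by default: synthetic
        grids have no depth variation).
        """
        from .preprocess import compute_size_factors, lognormalize_center

        real = family in _REAL or likelihood == "gau"
        if real:
            Y = lognormalize_center(dataset.counts()).Y_tilde
            nu = None
        else:
            Y = dataset.counts()
            nu = compute_size_factors(Y) if use_size_factors else dataset.nu
        return cls(Y, coords=dataset.X, family=family, L=L, T=T,
                   likelihood=likelihood, size_factors=nu,
                   feature_ids=dataset.feature_ids)

    # -- design (kernel precomputation) -------------------------------------

    def _prepare(self, config: FitConfig):
        """Precompute coordinate scaling and kernel factors (once per fit)."""
        d = {}
        if self.spatial:
            Xs, scale, offset = gp_core.rescale_coords(self.coords)
            ell = config.lengthscale if config.lengthscale is not None else 0.1
            spec = gp_core.KernelSpec(config.kernel_family, 1.0, ell)
            Z = gp_core.choose_inducing_points(
                Xs, M=config.M, strategy=config.ip_strategy, seed=config.seed)
            Kzz = gp_core.kernel_matrix(Z, Z, spec)
            L_u, jit = gp_core.chol_with_jitter(Kzz, ladder=(config.jitter,) + gp_core.JITTER_LADDER)
            Kzx = gp_core.kernel_matrix(Z, Xs, spec)
            from scipy.linalg import solve_triangular
            A_u = solve_triangular(L_u, Kzx, lower=True).T      # (N, M)
            d.update(
                Xs=Xs, coord_scale=scale, coord_offset=offset, spec=spec,
                Z=Z, L_u=L_u, A_u=A_u, A2=A_u ** 2,
                c_prior=np.clip(1.0 - np.sum(A_u ** 2, axis=1), 0.0, None),
                jitter=jit, M=Z.shape[0],
            )
        self._design = d
        return d

    # -- initialization ------------------------------------------------------

    def initialize(self, config: FitConfig | None = None) -> dict:
        """Build the initial parameter dictionary (SVD or NMF + Moran sort)."""
        config = config or FitConfig()
        des = self._prepare(config)
        rng = np.random.default_rng(config.seed)
        T, K, N, J, D = self.T, self.K, self.N, self.J, (
            self.coords.shape[1] if self.spatial else 0)
        params: dict[str, np.ndarray] = {}

        if self.nonneg:
            F0, W0 = training.init_nonneg(self.Y, self.L, seed=config.seed,
                                          size_factors=self.nu)
            if self.family == "nsfh" and 0 < T < self.L:
                F0, W0, _ = training.sort_components_by_moran(F0, W0, self.coords, T)
            colscale = np.clip(F0.mean(axis=0), 1e-12, None)
            F0 = F0 / colscale
            W0 = W0 * colscale
            logF0 = np.log(F0 + 1e-2)
            if T:
                params["Wp"] = np.log(W0[:, :T] + 1e-10)
            if K:
                params["Vp"] = np.log(W0[:, T:] + 1e-10)
            if self.likelihood == "nb":
                params["log_theta"] = np.full(J, np.log(10.0))
            spatial_target = logF0[:, :T] if T else None
            nonspatial_init = logF0[:, T:] if K else None
        else:
            F0, W0 = training.init_real(self.Y, self.L)
            if T:
                params["Wp"] = W0.copy()
                spatial_target = F0
                nonspatial_init = None
            else:
                params["Vp"] = W0.copy()
                spatial_target = None
                nonspatial_init = F0
            resid = self.Y - F0 @ W0.T
            params["log_sigma"] = 0.5 * np.log(resid.var(axis=0) + 1e-6)

        if T:
            Xd = np.column_stack([np.ones(N), des["Xs"]])
            beta, *_ = np.linalg.lstsq(Xd, spatial_target, rcond=None)
            params["beta0"] = beta[0].copy()
            params["beta1"] = beta[1:].reshape(des["Xs"].shape[1], T).copy()
            resid_f = spatial_target - Xd @ beta
            qmu, *_ = np.linalg.lstsq(des["A_u"], resid_f, rcond=None)
            params["qmu"] = qmu
            params["qls"] = np.full((des["M"], T), np.log(0.1))
            params["log_amp"] = np.zeros(T)
        if K:
            params["mh"] = nonspatial_init.copy()
            params["lsh"] = np.full((N, K), np.log(0.1))
            params["m"] = nonspatial_init.mean(axis=0)
            params["log_s"] = np.zeros(K)
        _ = rng  # seed reserved for stochastic init strategies
        self._params = params
        return params

    # -- ELBO and gradients --------------------------------------------------

    def _spatial_sample_moments(self, params, rows=None):
        """Variational marginal mean/sd of the spatial log-factors at rows."""
        des = self._design
        A_u = des["A_u"] if rows is None else des["A_u"][rows]
        A2 = des["A2"] if rows is None else des["A2"][rows]
        c = des["c_prior"] if rows is None else des["c_prior"][rows]
        Xs = des["Xs"] if rows is None else des["Xs"][rows]
        amp = np.exp(params["log_amp"])
        s = np.exp(params["qls"])
        proj = A_u @ params["qmu"]
        mean_x = params["beta0"] + Xs @ params["beta1"]
        mf = mean_x + amp * proj
        P = c[:, None] + A2 @ (s ** 2)
        sdf = amp * np.sqrt(np.clip(P, 1e-300, None))
        return mf, sdf, dict(A_u=A_u, A2=A2, Xs=Xs, amp=amp, s=s, proj=proj, P=P)

    def _loglik_and_grads(self, Yb, mub, params):
        """Per-entry log-likelihood sum, d/dmu, and likelihood-parameter grads."""
        lik = self.likelihood
        extra = {}
        if lik == "poi":
            ll = xlogy(Yb, mub) - mub - gammaln(Yb + 1.0)
            G = Yb / mub - 1.0
        elif lik == "nb":
            th = np.exp(params["log_theta"])
            ll = (gammaln(Yb + th) - gammaln(th) - gammaln(Yb + 1.0)
                  + th * np.log(th / (th + mub)) + xlogy(Yb, mub / (th + mub)))
            G = Yb / mub - (Yb + th) / (th + mub)
            dth = (digamma(Yb + th) - digamma(th) + np.log(th) + 1.0
                   - np.log(th + mub) - (Yb + th) / (th + mub))
            extra["log_theta"] = th * dth.sum(axis=0)
        else:
            s2 = np.exp(2.0 * params["log_sigma"])
            r = Yb - mub
            ll = -0.5 * np.log(2.0 * np.pi * s2) - r ** 2 / (2.0 * s2)
            G = r / s2
            extra["log_sigma"] = (r ** 2 / s2 - 1.0).sum(axis=0)
        return float(ll.sum()), G, extra

    def _elbo_and_grads(self, params, rng, n_samples: int, rows=None):
        """Monte-Carlo ELBO and analytic gradients w.r.t. every parameter.

        ``rows`` selects a minibatch; the expected log-likelihood (and its
        gradients) are rescaled by N/|batch| so the estimate stays unbiased.
        """
        T, K = self.T, self.K
        Yb = self.Y if rows is None else self.Y[rows]
        nub = self.nu if rows is None else self.nu[rows]
        Nb = Yb.shape[0]
        batch_scale = self.N / Nb

        grads = {k: np.zeros_like(v) for k, v in params.items()}
        if T:
            mf, sdf, sctx = self._spatial_sample_moments(params, rows)
            g_mf = np.zeros_like(mf)
            g_sdf = np.zeros_like(sdf)
        if K:
            mh = params["mh"] if rows is None else params["mh"][rows]
            lsh = params["lsh"] if rows is None else params["lsh"][rows]
            sdh = np.exp(lsh)
            g_mh = np.zeros_like(mh)
            g_lsh = np.zeros_like(lsh)
        if self.nonneg:
            W = np.exp(params["Wp"]) if T else np.zeros((self.J, 0))
            V = np.exp(params["Vp"]) if K else np.zeros((self.J, 0))
        else:
            W = params.get("Wp", np.zeros((self.J, 0)))
            V = params.get("Vp", np.zeros((self.J, 0)))
        dW = np.zeros_like(W)
        dV = np.zeros_like(V)
        lik_extra_acc: dict[str, np.ndarray] = {}

        loglik_acc = 0.0
        for _ in range(n_samples):
            if T:
                epsF = rng.standard_normal(mf.shape)
                F = mf + sdf * epsF
                aF = np.exp(F) if self.nonneg else F
            if K:
                epsH = rng.standard_normal(mh.shape)
                H = mh + sdh * epsH
                aH = np.exp(H) if self.nonneg else H
            lam = np.zeros((Nb, self.J))
            if T:
                lam += aF @ W.T
            if K:
                lam += aH @ V.T
            if self.likelihood in _COUNT_LIKS:
                mub = nub[:, None] * lam
            else:
                mub = lam
            ll, Gmu, extra = self._loglik_and_grads(Yb, mub, params)
            loglik_acc += ll
            Glam = Gmu * nub[:, None] if self.likelihood in _COUNT_LIKS else Gmu
            if T:
                dW += Glam.T @ aF
                GF = (Glam @ W) * (aF if self.nonneg else 1.0)
                g_mf += GF
                g_sdf += GF * epsF
            if K:
                dV += Glam.T @ aH
                GH = (Glam @ V) * (aH if self.nonneg else 1.0)
                g_mh += GH
                g_lsh += GH * epsH * sdh
            for k, v in extra.items():
                lik_extra_acc[k] = lik_extra_acc.get(k, 0.0) + v

        inv = batch_scale / n_samples
        loglik = loglik_acc * inv
        dW *= inv
        dV *= inv
        for k, v in lik_extra_acc.items():
            grads[k] += v * inv

        if self.nonneg:
            if T:
                grads["Wp"] += dW * W
            if K:
                grads["Vp"] += dV * V
        else:
            if T:
                grads["Wp"] += dW
            if K:
                grads["Vp"] += dV

        elbo = loglik

        if T:
            g_mf *= inv
            g_sdf *= inv
            A_u, A2, Xs = sctx["A_u"], sctx["A2"], sctx["Xs"]
            amp, s, proj, P = sctx["amp"], sctx["s"], sctx["proj"], sctx["P"]
            grads["beta0"] += g_mf.sum(axis=0)
            grads["beta1"] += Xs.T @ g_mf
            grads["qmu"] += amp * (A_u.T @ g_mf)
            grads["log_amp"] += (g_mf * (amp * proj)).sum(axis=0) + (g_sdf * sdf).sum(axis=0)
            tmp = g_sdf * amp / np.sqrt(np.clip(P, 1e-300, None))
            grads["qls"] += (A2.T @ tmp) * (s ** 2)
            # whitened KL per spatial component
            s_full = np.exp(params["qls"])
            kl_sp = 0.5 * np.sum(params["qmu"] ** 2 + s_full ** 2 - 1.0 - 2.0 * params["qls"])
            elbo -= kl_sp
            grads["qmu"] -= params["qmu"]
            grads["qls"] -= (s_full ** 2 - 1.0)

        if K:
            g_mh *= inv
            g_lsh *= inv
            if rows is None:
                grads["mh"] += g_mh
                grads["lsh"] += g_lsh
            else:
                np.add.at(grads["mh"], rows, g_mh)
                np.add.at(grads["lsh"], rows, g_lsh)
            m, ls = params["m"], params["log_s"]
            s2p = np.exp(2.0 * ls)
            dmu = params["mh"] - m
            sdh_full = np.exp(params["lsh"])
            kl_ns = 0.5 * np.sum(
                (dmu ** 2 + sdh_full ** 2) / s2p - 1.0 - 2.0 * params["lsh"] + 2.0 * ls
            )
            elbo -= kl_ns
            grads["mh"] -= dmu / s2p
            grads["lsh"] -= (sdh_full ** 2 / s2p - 1.0)
            grads["m"] += dmu.sum(axis=0) / s2p
            grads["log_s"] += ((dmu ** 2 + sdh_full ** 2) / s2p - 1.0).sum(axis=0)

        return elbo, grads

    def elbo_estimate(self, params=None, seed: int = 0, n_samples: int = 3, rows=None,
                      config: FitConfig | None = None) -> float:
        """Unbiased Monte-Carlo ELBO estimate (repeatable given ``seed``)."""
        if self._design is None:
            self._prepare(config or FitConfig())
        if params is None:
            params = self._params if self._params is not None else self.initialize(config)
        rng = np.random.default_rng(seed)
        elbo, _ = self._elbo_and_grads(params, rng, n_samples, rows=rows)
        return elbo

    # -- fitting -------------------------------------------------------------

    def fit(self, config: FitConfig | None = None, **kwargs) -> "SpatialFactorResults":
        """Maximize the ELBO with Adam; returns a results object.

        Keyword arguments override :class:`FitConfig` fields.
        """
        config = replace(config or FitConfig(), **kwargs) if kwargs else (config or FitConfig())
        params = self.initialize(config)
        params = {k: v.astype(float).copy() for k, v in params.items()}
        opt = training.Adam(params, lr=config.learning_rate)
        rng = np.random.default_rng(config.seed)
        trace = training.TraceLog()
        batch = config.batch_size
        if batch is None:
            batch = self.N if self.N <= 3000 else 1000
        full_batch = batch >= self.N
        checkpoint = copy.deepcopy(params)
        aborted = False

        for it in range(1, config.max_iter + 1):
            rows = None if full_batch else np.sort(rng.choice(self.N, size=batch, replace=False))
            elbo, grads = self._elbo_and_grads(params, rng, config.n_samples_elbo, rows=rows)
            if not np.isfinite(elbo):
                warnings.warn(
                    f"non-finite objective at iteration {it}; reverting to last checkpoint")
                params = checkpoint
                aborted = True
                break
            trace.append(it, -elbo)
            opt.step(params, {k: -g for k, g in grads.items()})
            if it % 50 == 0:
                checkpoint = copy.deepcopy(params)
            if it >= config.conv_start and (it - config.conv_start) % config.conv_stride == 0:
                now, prev = training._smoothed_pair(
                    np.asarray(trace.objective), it, config.conv_stride, config.conv_window)
                trace.smoothed[it] = now
                rel = abs(now - prev) / abs(prev) if prev != 0 else abs(now - prev)
                if rel < config.conv_tol:
                    trace.converged_at = it
                    break

        self._params = params
        return SpatialFactorResults(self, params, trace, config, aborted=aborted)


# ---------------------------------------------------------------------------
# Results


class SpatialFactorResults:
    """Fitted-model state: loadings, factor posteriors, trace, predictions."""

    def __init__(self, model: SpatialFactorModel, params: dict,
                 trace: training.TraceLog, config: FitConfig, aborted: bool = False):
        self.model = model
        self.params = params
        self.trace = trace
        self.config = config
        self.aborted = aborted

    # loadings ---------------------------------------------------------------

    @property
    def W(self) -> np.ndarray:
        """Spatial loadings, (J, T); nonnegative for nonneg families."""
        if self.model.T == 0:
            return np.zeros((self.model.J, 0))
        Wp = self.params["Wp"]
        return np.exp(Wp) if self.model.nonneg else Wp

    @property
    def V(self) -> np.ndarray:
        """Nonspatial loadings, (J, L - T)."""
        if self.model.K == 0:
            return np.zeros((self.model.J, 0))
        Vp = self.params["Vp"]
        return np.exp(Vp) if self.model.nonneg else Vp

    @property
    def loadings(self) -> np.ndarray:
        """All loadings, spatial block first, (J, L)."""
        return np.hstack([self.W, self.V])

    # factors ----------------------------------------------------------------

    def factor_posteriors(self, X_new=None):
        """Posterior mean/variance of spatial and nonspatial latent factors.

        Returns (mf, vf, mh, vh): spatial moments at training coordinates
        (or ``X_new``), nonspatial variational moments at training rows
        (prior moments when ``X_new`` is given, since nonspatial factors
        are undefined off-sample).
        """
        m = self.model
        mf = vf = mh = vh = None
        if m.T:
            if X_new is None:
                mfv, sdf, _ = m._spatial_sample_moments(self.params)
                mf, vf = mfv, sdf ** 2
            else:
                mf, vf = self._spatial_moments_at(X_new)
        if m.K:
            if X_new is None:
                mh = self.params["mh"]
                vh = np.exp(2.0 * self.params["lsh"])
            else:
                n_new = np.atleast_2d(np.asarray(X_new)).shape[0]
                mh = np.broadcast_to(self.params["m"], (n_new, m.K)).copy()
                vh = np.broadcast_to(np.exp(2.0 * self.params["log_s"]), (n_new, m.K)).copy()
        return mf, vf, mh, vh

    def _spatial_moments_at(self, X_new):
        """Whitened-SVGP predictive moments of each spatial component at X_new."""
        from scipy.linalg import solve_triangular

        m, des, p = self.model, self.model._design, self.params
        Xq = (np.atleast_2d(np.asarray(X_new, dtype=float)) - des["coord_offset"]) / des["coord_scale"]
        Kzq = gp_core.kernel_matrix(des["Z"], Xq, des["spec"])
        C = solve_triangular(des["L_u"], Kzq, lower=True)       # (M, Nq)
        amp = np.exp(p["log_amp"])
        s = np.exp(p["qls"])
        mean = p["beta0"] + Xq @ p["beta1"] + amp * (C.T @ p["qmu"])
        base = np.clip(1.0 - np.sum(C ** 2, axis=0), 0.0, None)
        var = (amp ** 2) * (base[:, None] + (C ** 2).T @ (s ** 2))
        return mean, np.clip(var, 1e-12, None)

    def factors(self, X_new=None):
        """Point estimates of the factors on the model's natural scale.

        Nonnegative families return arithmetic lognormal means
        exp(mean + var/2) of the variational marginals; real families
        return posterior means. Returns (F, H) blocks ((n, T) and (n, K)).
        """
        m = self.model
        mf, vf, mh, vh = self.factor_posteriors(X_new)
        n = m.N if X_new is None else np.atleast_2d(np.asarray(X_new)).shape[0]
        if m.T:
            F = np.exp(mf + vf / 2.0) if m.nonneg else mf
        else:
            F = np.zeros((n, 0))
        if m.K:
            H = np.exp(mh + vh / 2.0) if m.nonneg else mh
        else:
            H = np.zeros((n, 0))
        return F, H

    # predictions ------------------------------------------------------------

    def predict_mean(self, X_new=None, size_factors=None) -> np.ndarray:
        """Predicted data mean at arbitrary coordinates (or in-sample).

        Count families return nu_i * lambda_ij (strictly positive);
        Gaussian families return the normalized-scale mean. Off-sample,
        nonspatial factors contribute their prior/posterior means.
        """
        m = self.model
        F, H = self.factors(X_new)
        n = F.shape[0] if m.T else H.shape[0]
        lam = np.zeros((n, m.J))
        if m.T:
            lam += F @ self.W.T
        if m.K:
            lam += H @ self.V.T
        if m.likelihood in _COUNT_LIKS:
            nu = np.ones(n) if size_factors is None else np.asarray(size_factors, dtype=float)
            if X_new is None and size_factors is None:
                nu = m.nu
            return nu[:, None] * np.clip(lam, 1e-12, None)
        return lam

    # postprocessing ---------------------------------------------------------

    def simplex(self, style: str = "spde"):
        """Simplex-projected factorization of the in-sample (F, W) blocks."""
        from . import postprocess

        if not self.model.nonneg:
            raise InvalidArgumentError("simplex postprocessing applies to nonnegative families")
        F, H = self.factors()
        A = np.hstack([F, H])
        B = self.loadings
        if style == "spde":
            return postprocess.project_simplex_spde(A, B)
        if style == "lda":
            return postprocess.project_simplex_lda(A, B)
        raise InvalidArgumentError(f"unknown style {style!r}")

    def gene_spatial_scores(self) -> np.ndarray:
        """Spatial importance score per feature, in [0, 1]."""
        from . import postprocess

        F, H = self.factors()
        return postprocess.gene_spatial_scores(self.W, self.V, F, H)

    def observation_spatial_scores(self) -> np.ndarray:
        """Spatial importance score per observation, in [0, 1]."""
        from . import postprocess

        F, H = self.factors()
        return postprocess.observation_spatial_scores(F, H, self.W, self.V)

    # reporting --------------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = [
            "SpatialFactorModel results",
            "=" * 40,
            f"family:            {m.family.upper()}",
            f"likelihood:        {m.likelihood}",
            f"components (L/T):  {m.L}/{m.T}",
            f"observations (N):  {m.N}",
            f"features (J):      {m.J}",
        ]
        if m.spatial:
            des = m._design
            lines.append(f"inducing points:   {des['M']} ({self.config.ip_strategy})")
            lines.append(f"kernel:            {des['spec'].family} "
                         f"(lengthscale {des['spec'].lengthscale:g} of domain)")
        lines.append(f"iterations run:    {len(self.trace.objective)}")
        conv = self.trace.converged_at
        lines.append(f"converged at:      {conv if conv is not None else 'not converged'}")
        if self.trace.objective:
            lines.append(f"final objective:   {self.trace.objective[-1]:.4f}")
        return "\n".join(lines)
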