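"""Model families: rates, likelihoods, ELBO correctness and predictions."""

import numpy as np
import pytest

from nsfkit.exceptions import InvalidArgumentError, InvalidStateError
from nsfkit.factor_models import (
    FitConfig,
    SpatialFactorModel,
    log_likelihood,
    rate_matrix,
)


class TestRateMatrix:
    def test_hand_arithmetic(self):
        lam = rate_matrix(W=[[2.0]], V=[[3.0]], F_draw=[[0.0]],
                          H_draw=[[np.log(2.0)]], nu=[1.0])
        assert lam[0, 0] == pytest.approx(8.0)

    def test_special_cases_reduce(self, rng):
        N, J, T = 5, 4, 3
        F = rng.standard_normal((N, T))
        W = rng.uniform(0, 1, (J, T))
        nu = rng.uniform(0.5, 2, N)
        full = rate_matrix(W, np.zeros((J, 0)), F, np.zeros((N, 0)), nu)
        np.testing.assert_allclose(full, nu[:, None] * (np.exp(F) @ W.T))

    def test_size_factor_linearity(self, rng):
        F = rng.standard_normal((4, 2))
        W = rng.uniform(0, 1, (3, 2))
        lam1 = rate_matrix(W, np.zeros((3, 0)), F, np.zeros((4, 0)), np.ones(4))
        lam3 = rate_matrix(W, np.zeros((3, 0)), F, np.zeros((4, 0)), 3 * np.ones(4))
        np.testing.assert_allclose(lam3, 3 * lam1)

    def test_negative_loadings_rejected(self):
        with pytest.raises(InvalidStateError):
            rate_matrix([[-1.0]], np.zeros((1, 0)), [[0.0]], np.zeros((1, 0)), [1.0])


class TestLogLikelihood:
    def test_poisson_values(self):
        assert log_likelihood([[0.0]], [[1.0]], "poi")[0, 0] == pytest.approx(-1.0)
        val = log_likelihood([[2.0]], [[2.0]], "poi")[0, 0]
        assert val == pytest.approx(np.log(2) - 2)

    def test_nb_converges_to_poisson(self, rng):
        y = rng.poisson(3.0, (4, 5)).astype(float)
        mu = rng.uniform(0.5, 5, (4, 5))
        nb = log_likelihood(y, mu, "nb", theta=np.full(5, 1e8))
        poi = log_likelihood(y, mu, "poi")
        np.testing.assert_allclose(nb, poi, atol=1e-4)

    def test_gaussian_matches_scipy(self, rng):
        from scipy.stats import norm

        y = rng.standard_normal((3, 2))
        mu = rng.standard_normal((3, 2))
        s2 = np.array([0.5, 2.0])
        ours = log_likelihood(y, mu, "gau", sigma2=s2)
        ref = norm.logpdf(y, mu, np.sqrt(s2))
        np.testing.assert_allclose(ours, ref, rtol=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(InvalidStateError):
            log_likelihood([[1.0]], [[0.0]], "poi")


def _tiny_count_data(rng, N=15, J=6):
    X = rng.uniform(0, 1, (N, 2))
    Y = rng.poisson(2.0, (N, J)).astype(float)
    return Y, X


class TestSpecialCaseEquivalence:
    """NSFH with T = L (or T = 0) is exactly NSF (or PNMF)."""

    @pytest.mark.parametrize("T,family", [(3, "nsf"), (0, "pnmf")])
    def test_elbo_identical_on_same_draws(self, rng, T, family):
        Y, X = _tiny_count_data(rng)
        cfg = FitConfig(seed=5, lengthscale=0.3)
        hybrid = SpatialFactorModel(Y, coords=X, family="nsfh", L=3, T=T)
        pure = SpatialFactorModel(Y, coords=X, family=family, L=3)
        ph = hybrid.initialize(cfg)
        pp_ = pure.initialize(cfg)
        for k in ph:
            np.testing.assert_allclose(ph[k], pp_[k])
        eh = hybrid.elbo_estimate(seed=11, config=cfg)
        ep = pure.elbo_estimate(seed=11, config=cfg)
        assert eh == pytest.approx(ep, rel=1e-12)


class TestPermutationInvariance:
    def test_nonspatial_elbo_invariant_under_row_permutation(self, rng):
        """PNMF has no spatial terms: permuting observations (with data and
        variational state permuted consistently) leaves the ELBO unchanged.
        Variational variances are shrunk so the Monte-Carlo term is
        effectively deterministic."""
        Y, X = _tiny_count_data(rng)
        cfg = FitConfig(seed=2)
        mod = SpatialFactorModel(Y, family="pnmf", L=2)
        params = mod.initialize(cfg)
        params["lsh"][:] = -20.0
        e1 = mod.elbo_estimate(params, seed=3)
        perm = rng.permutation(Y.shape[0])
        mod2 = SpatialFactorModel(Y[perm], family="pnmf", L=2)
        mod2.initialize(cfg)
        p2 = {k: v.copy() for k, v in params.items()}
        p2["mh"] = params["mh"][perm]
        p2["lsh"] = params["lsh"][perm]
        e2 = mod2.elbo_estimate(p2, seed=9)
        assert e2 == pytest.approx(e1, rel=1e-6)

    def test_spatial_elbo_changes_when_coords_shuffle(self, rng):
        Y, X = _tiny_count_data(rng)
        cfg = FitConfig(seed=2, lengthscale=0.3)
        mod = SpatialFactorModel(Y, coords=X, family="nsf", L=2)
        params = mod.initialize(cfg)
        params["qls"][:] = -20.0
        e1 = mod.elbo_estimate(params, seed=3)
        perm = rng.permutation(Y.shape[0])
        mod2 = SpatialFactorModel(Y, coords=X[perm], family="nsf", L=2)
        mod2._prepare(cfg)
        e2 = mod2.elbo_estimate(params, seed=3)
        assert abs(e1 - e2) > 1e-6


class TestElboEstimator:
    def test_unbiased_under_minibatching(self, rng):
        """Full-batch and averaged half-batch ELBOs agree in expectation."""
        Y = rng.standard_normal((6, 3))
        mod = SpatialFactorModel(Y, family="fa", L=2)
        cfg = FitConfig(seed=0)
        params = mod.initialize(cfg)
        rows1, rows2 = np.arange(3), np.arange(3, 6)
        full, halves = [], []
        for s in range(200):
            full.append(mod.elbo_estimate(params, seed=s, n_samples=1))
            a = mod.elbo_estimate(params, seed=1000 + s, n_samples=1, rows=rows1)
            b = mod.elbo_estimate(params, seed=2000 + s, n_samples=1, rows=rows2)
            halves.append((a + b) / 2.0)
        full, halves = np.array(full), np.array(halves)
        se = np.sqrt(full.var() / 200 + halves.var() / 200)
        assert abs(full.mean() - halves.mean()) < 3 * max(se, 1e-12)

    def test_gaussian_elbo_approaches_plugin_at_zero_variance(self, rng):
        Y = rng.standard_normal((5, 3))
        mod = SpatialFactorModel(Y, family="fa", L=2)
        cfg = FitConfig(seed=1)
        params = mod.initialize(cfg)
        params["lsh"][:] = -20.0
        from nsfkit.factor_models import log_likelihood as ll

        mu = params["mh"] @ params["Vp"].T
        plug = ll(Y, mu, "gau", sigma2=np.exp(2 * params["log_sigma"])).sum()
        m, s_p = params["m"], np.exp(params["log_s"])
        dmu = params["mh"] - m
        kl = 0.5 * np.sum((dmu ** 2 + np.exp(2 * params["lsh"])) / s_p ** 2
                          - 1.0 - 2.0 * params["lsh"] + 2.0 * params["log_s"])
        elbo = mod.elbo_estimate(params, seed=4, n_samples=2)
        assert elbo == pytest.approx(plug - kl, rel=1e-8)

    def test_inflating_kl_decreases_elbo(self, rng):
        """With one component's loadings driven to ~0, shifting that
        component's variational mean changes only the KL term; the ELBO
        must drop by exactly that KL increase."""
        Y, X = _tiny_count_data(rng)
        cfg = FitConfig(seed=0, lengthscale=0.3)
        mod = SpatialFactorModel(Y, coords=X, family="nsf", L=2)
        params = mod.initialize(cfg)
        base = {k: v.copy() for k, v in params.items()}
        base["Wp"][:, 0] = -300.0  # component 0 contributes nothing to lambda
        infl = {k: v.copy() for k, v in base.items()}
        infl["qmu"] = base["qmu"].copy()
        infl["qmu"][:, 0] += 2.0
        dkl = 0.5 * (np.sum(infl["qmu"] ** 2) - np.sum(base["qmu"] ** 2))
        assert dkl > 0
        e_base = mod.elbo_estimate(base, seed=7)
        e_infl = mod.elbo_estimate(infl, seed=7)
        assert e_infl < e_base
        assert e_base - e_infl == pytest.approx(dkl, rel=1e-8)


class TestGradients:
    @pytest.mark.parametrize("family,lik,T", [
        ("nsfh", "nb", 2), ("nsf", "poi", 3), ("rsf", "gau", 3), ("fa", "gau", 0),
    ])
    def test_analytic_gradients_match_finite_differences(self, rng, family, lik, T):
        Y, X = _tiny_count_data(rng)
        kwargs = {"T": T} if family == "nsfh" else {}
        lik_arg = None if family in ("rsf", "fa") else lik
        mod = SpatialFactorModel(Y, coords=X, family=family, L=3,
                                 likelihood=lik_arg, **kwargs)
        cfg = FitConfig(seed=3, lengthscale=0.3)
        params = mod.initialize(cfg)

        def elbo(ps):
            r = np.random.default_rng(11)
            e, _ = mod._elbo_and_grads(ps, r, 2)
            return e

        _, grads = mod._elbo_and_grads(params, np.random.default_rng(11), 2)
        eps = 1e-5
        check_rng = np.random.default_rng(0)
        for k, p in params.items():
            flat_idx = check_rng.choice(p.size, size=min(3, p.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                hi = {kk: vv.copy() for kk, vv in params.items()}
                lo = {kk: vv.copy() for kk, vv in params.items()}
                hi[k][idx] += eps
                lo[k][idx] -= eps
                num = (elbo(hi) - elbo(lo)) / (2 * eps)
                an = grads[k][idx]
                assert num == pytest.approx(an, rel=1e-3, abs=1e-4), f"{k}[{idx}]"


class TestPredictMean:
    def test_lognormal_correction_matches_monte_carlo(self, rng):
        Y, X = _tiny_count_data(rng)
        cfg = FitConfig(seed=0, lengthscale=0.3)
        mod = SpatialFactorModel(Y, coords=X, family="nsf", L=2)
        params = mod.initialize(cfg)
        mod._params = params
        from nsfkit.factor_models import SpatialFactorResults
        from nsfkit.training import TraceLog

        res = SpatialFactorResults(mod, params, TraceLog(), cfg)
        mf, vf, _, _ = res.factor_posteriors()
        F, _ = res.factors()
        draws = np.exp(mf[None] + np.sqrt(vf)[None] * rng.standard_normal((200_000,) + mf.shape))
        np.testing.assert_allclose(F, draws.mean(axis=0), rtol=5e-3)

    def test_zeroed_loading_column_contributes_nothing(self, rng):
        Y, X = _tiny_count_data(rng)
        cfg = FitConfig(seed=0, lengthscale=0.3)
        mod = SpatialFactorModel(Y, coords=X, family="nsf", L=2)
        params = mod.initialize(cfg)
        mod._params = params
        from nsfkit.factor_models import SpatialFactorResults
        from nsfkit.training import TraceLog

        res = SpatialFactorResults(mod, params, TraceLog(), cfg)
        mu_full = res.predict_mean(X)
        p2 = {k: v.copy() for k, v in params.items()}
        p2["Wp"][:, 0] = -np.inf
        res2 = SpatialFactorResults(mod, p2, TraceLog(), cfg)
        mu_wo = res2.predict_mean(X)
        F, _ = res.factors()
        W = res.W
        expected = mu_full - F[:, [0]] @ W.T[[0]]
        # atol absorbs cancellation where a feature loads almost entirely
        # on the removed component
        np.testing.assert_allclose(mu_wo, np.clip(expected, 1e-12, None),
                                   rtol=1e-6, atol=1e-9)

    def test_predictions_positive_for_count_families(self, rng):
        Y, X = _tiny_count_data(rng)
        mod = SpatialFactorModel(Y, coords=X, family="nsfh", L=2, T=1)
        res = mod.fit(FitConfig(seed=0, max_iter=5, lengthscale=0.3))
        Xnew = rng.uniform(0, 1, (6, 2))
        mu = res.predict_mean(Xnew)
        assert mu.shape == (6, Y.shape[1])
        assert np.all(mu > 0)


class TestModelValidation:
    def test_family_and_likelihood_consistency(self, rng):
        Y, X = _tiny_count_data(rng)
        with pytest.raises(InvalidArgumentError):
            SpatialFactorModel(Y, coords=X, family="fa", likelihood="poi")
        with pytest.raises(InvalidArgumentError):
            SpatialFactorModel(Y, coords=X, family="nsf", likelihood="gau")
        with pytest.raises(InvalidArgumentError):
            SpatialFactorModel(Y, family="nsf", L=2)  # missing coords
        with pytest.raises(InvalidArgumentError):
            SpatialFactorModel(Y, coords=X, family="phantom")
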