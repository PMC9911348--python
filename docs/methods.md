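# Methods

This note records the models implemented in `nsfkit`, the inference
algorithm, every default that is a package choice rather than a published
constant, the synthetic-data generators, and known limitations.

## 1. Model families

Let `Y` be an `N × J` matrix of counts at coordinates `X` (`N × D`), with
positive size factors `nu` (default: all ones). All families model a rank-`L`
mean; `T` of the `L` components are *spatial*, the remaining `K = L − T`
*nonspatial*.

**Count families (`pnmf`, `nsf`, `nsfh`).**

```
y_ij ~ Poisson(nu_i * lambda_ij)          (or negative binomial, below)
lambda_ij = sum_{l<=T} w_jl exp(f_il) + sum_{l>T} v_jl exp(h_il)
```

Loadings `W` (`J × T`) and `V` (`J × K`) are nonnegative, parameterized as
exponentials of unconstrained reals so they stay strictly positive. Each
spatial log-factor has a GP prior

```
f_l ~ GP(beta_0l + x' beta_1l,  k_l),    k_l(x, x') = a_l^2 (1 + sqrt(3) r / ell)(exp(-sqrt(3) r / ell)),
```

a Matérn 3/2 kernel with per-component amplitude `a_l` and shared
lengthscale `ell` (see §3). Nonspatial log-factors get independent
`N(m_l, s_l^2)` priors whose parameters are learned. `nsfh` with `0 < T < L`
is the hybrid; `T = L` is `nsf`, `T = 0` is `pnmf`, and the implementation
realizes these as literally the same code path (verified by exact ELBO
equality in the tests).

The negative binomial option (`likelihood="nb"`) has per-feature shape
`theta_j` (variance `mu + mu^2/theta`), optimized on the log scale,
initialized at `theta = 10`.

**Real-valued families (`fa`, `rsf`).** Gaussian likelihood with per-feature
variance `sigma_j^2` on the median-ratio normalized, `log1p`-transformed,
feature-centered matrix (§4). `rsf` puts the same GP priors directly on the
real-valued factors; `fa` is a classical factor-analysis analog. Factors and
loadings enter linearly (no `exp`).

## 2. Inference

The posterior over factors is approximated variationally and the evidence
lower bound (ELBO) maximized.

**Spatial components: whitened inducing points.** Each spatial component has
`M` inducing locations `Z` (default: all unique training coordinates). With
`K_zz = L_chol L_chol'`, the variational posterior is placed on the whitened
variable `u_white = L_chol^{-1}(u − mean(Z))`, i.e. `q(u_white) = N(q_mu, S)`
with `S = diag(exp(qls))^2` during optimization (a diagonal covariance
root; full roots are supported by the GP core and used in the oracle
tests). Whitening makes the KL term `0.5 * (||q_mu||^2 + ||S||_F^2 − M −
2 log|S|)` independent of the kernel, and it lets the amplitude `a_l`
factor out linearly: predictive moments at any `x` are

```
mean = beta_0 + x' beta_1 + a * A(x) q_mu,      A(x) = (L_chol^{-1} k(Z, x))'
var  = a^2 * (1 − ||A(x)||^2 + A(x)^2 · s^2)
```

Because the lengthscale is fixed (§3), `L_chol` and the `N × M` matrix `A`
are computed once per fit; every iteration afterwards costs dense matrix
products only.

**Objective and gradients.** The expected log-likelihood is estimated with
Monte-Carlo reparameterized draws of the factors (default 3 per iteration).
All gradients — variational means/log-sds, mean-function coefficients,
log-amplitudes, loadings, likelihood shapes — are derived analytically and
verified against central finite differences in the test suite. Minibatches
(rows) rescale the likelihood term by `N/|batch|`, keeping the estimator
unbiased; KL terms are always summed in full.

**Optimization.** Adam (learning rate 0.01), full batch for `N ≤ 3000`,
otherwise 1000 rows per step. Initialization: scikit-learn NMF (`nndsvda`)
on size-factor-adjusted counts for nonnegative families (columns rescaled to
unit mean factor activity), truncated SVD for real families; spatial
variational means are seeded by least squares of the initialized log-factors
on the mean function and whitened basis. For hybrids, components are
assigned to the spatial block in decreasing order of Moran's I of the
initial factors. A non-finite objective aborts the run and reverts to the
last checkpoint (kept every 50 iterations).

**Convergence.** Starting at iteration 110 and every 10 iterations, a cubic
polynomial is least-squares fitted to the last 100 raw objective values
(iteration index centered and scaled to [−1, 1] for conditioning); the fit
is evaluated at the current and the previous check's iteration, and
optimization stops when the relative change between those smoothed values
drops below 5e-5. The rule is scale-invariant.

## 3. Defaults that are package choices

- **Kernel lengthscale is fixed, not optimized**: coordinates are rescaled
  so the longest side of their bounding box is 1, and `ell = 0.1` of that
  domain. Rationale: it matches the scale of tissue-level patterns, it is
  what makes the one-time whitened precomputation (and hence a pure
  NumPy implementation) fast, and amplitudes — which *are* optimized per
  component — absorb most per-component flexibility. `FitConfig(lengthscale=...)`
  overrides it.
- **Amplitude optimized on the log scale**, initialized at 1.
- **Diagonal whitened covariance root** during optimization (initial sd
  0.1); full roots only in the GP core API.
- **Inducing points**: every unique training coordinate (`strategy="all"`).
  k-means (`"kmeans"`) and subsampling (`"random"`) are available when
  `M < N` is needed.
- **ELBO samples 3, Adam lr 0.01, max 1000 iterations** — conventional
  values, recorded in `FitConfig`; none were tuned to any benchmark.
- **Jitter**: Cholesky attempts a ladder `1e-6, 1e-4, 1e-2` (times squared
  amplitude) before raising a numerical error naming the failure.
- **Size factors default to 1** for simulated grids (no depth variation);
  median-ratio factors are available (`use_size_factors=True`, or
  `--size-factors` on the CLI) and are computed from the full matrix before
  gene selection.

## 4. Preprocessing

- **Gene ranking**: Poisson deviance of each gene against a constant-rate
  null scaled by size factors; top-`n` genes kept.
- **Normalization (real families)**: counts scaled to the median total per
  observation, `log1p`, then feature centering. The inverse transform
  (used when scoring Gaussian fits on the count scale) exponentiates,
  subtracts 1, clips at 1e-8, and rescales by each observation's total.
- **Split**: uniformly random 5% validation split (banker's rounding:
  1296 locations → 65 validation / 1231 training).

## 5. Synthetic data generators

Both scenarios use a 36 × 36 grid (N = 1296) and negative binomial
observation noise with shape 10 (gamma–Poisson sampling), background mean
0.2.

- **Pattern libraries**: `ggblocks` — four disjoint binary shapes (block,
  two bars, cross); `quilt` — four overlapping rectangles; `both`
  concatenates them (eight patterns). Every pattern covers ≈ 20% of the
  grid (252–288 cells). That coverage is a deliberate design constant: the
  nonspatial factors are Bernoulli(0.2), so spatial and nonspatial
  components have equal mean activity and the expected true gene score in
  the mixed design is the weight share `12/(12+8) = 0.6`.
- **Scenario I** (all genes spatial): each of `J = 200` genes loads 20.0 on
  exactly one pattern (one-hot), giving active mean entries of exactly
  20.2.
- **Scenario II** (`J = 500`): *split* mode — half the genes load 20.0 on a
  spatial pattern, half on a nonspatial factor (3 factors; 6 for `both`);
  *mixed* mode — every gene loads 12.0 on one spatial and 8.0 on one
  nonspatial component. True gene scores are computed from the truth
  matrices by the same simplex postprocessing used for fits.
- Ground truth (factors, loadings, mean matrix, scores) is returned with
  every dataset and written alongside exported bundles.

## 6. Postprocessing and metrics

- **Simplex projection**: SPDE-style (factor columns sum to 1, loading rows
  sum to 1, per-feature scale `w_bar`) and LDA-style (roles switched,
  per-observation scale). Both leave the likelihood invariant.
- **Gene spatial score** `gamma_j`: SPDE-projection of the concatenated
  blocks `[F, H], [W, V]`, then the sum of the first `T` projected loadings;
  `rho_i` for observations uses the LDA projection of the factors. Factor
  point estimates entering these are arithmetic lognormal means
  `exp(mean + var/2)` of the variational marginals.
- **Benchmark metrics**: mean (over observations) of the feature-summed
  Poisson deviance on held-out counts (Gaussian fits are inverted to the
  count scale first); RMSE; minimum over true components of the best
  absolute Pearson correlation to any fitted component; loadings sparsity;
  Moran's I of factors on a symmetric binary 6-NN graph; Euclidean distance
  between fitted and true gene scores.

## 7. Limitations

- The lengthscale is not learned; strongly multi-scale data would need a
  per-component or optimized lengthscale (and with it a per-iteration
  Cholesky).
- Whitened covariance roots are diagonal during optimization; posterior
  correlations between inducing values are not represented in fits.
- Full-batch fits hold the `N × M` whitened basis densely in memory;
  beyond ~10⁴ locations use `M < N` inducing points and minibatches.
- The smoothed-trace stopping rule can declare convergence on long plateaus
  of a slowly improving fit; the iteration cap is a real budget, and
  benchmark comparisons in the tests use fixed iteration budgets rather
  than the stopper.
- Gaussian-family deviances on the count scale depend on the inverse
  normalization convention (§4) and are comparable across Gaussian fits,
  not directly against count-likelihood training objectives.
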