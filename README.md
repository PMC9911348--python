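# nsfkit

Nonnegative spatial factorization for spatial transcriptomics count data.

Spatial transcriptomics assays measure transcript counts for thousands of
genes at known spatial locations. `nsfkit` decomposes such a counts matrix
into a small number of nonnegative *factors* (spatial activity patterns over
locations) and *loadings* (each gene's weight on every pattern), with the
spatial patterns regularized by Gaussian-process priors so they vary
smoothly over the tissue. The package implements the nonnegative spatial
factorization model family of Townes & Engelhardt (*Nature Methods*, 2023),
with five members sharing one low-rank mean structure:

| family | likelihood | factors | spatial prior |
|--------|------------|---------|---------------|
| `fa`   | Gaussian   | real-valued | none |
| `pnmf` | Poisson/NB | nonnegative | none |
| `rsf`  | Gaussian   | real-valued | GP (Matérn 3/2) |
| `nsf`  | Poisson/NB | nonnegative | GP (Matérn 3/2) |
| `nsfh` | Poisson/NB | nonnegative | GP on T of L components |

For the count families the mean is
`E[y_ij] = nu_i * (sum_{l<=T} w_jl exp(f_il) + sum_{l>T} v_jl exp(h_il))`,
where the log-factors `f_l` carry GP priors over the coordinates and `h_l`
are unconstrained ("nonspatial") factors. The hybrid `nsfh` reduces exactly
to `nsf` at `T = L` and to `pnmf` at `T = 0`. After fitting, a simplex
normalization of the factorization yields an interpretable per-gene
**spatial importance score** in [0, 1]: the fraction of a gene's expression
explained by the spatial components.

Inference is variational: whitened inducing-point posteriors for the GP
components, Monte-Carlo evidence lower bound with analytic reparameterized
gradients, Adam optimization, and a smoothed-trace stopping rule. The
engine is pure NumPy/SciPy.

## Worked example

Simulate a dataset in which 250 of 500 genes follow smooth spatial patterns
(a 36×36 grid, overlapping "quilt" patches) and the other 250 follow
nonspatial Bernoulli programs, then recover the split with a hybrid model:

```python
from nsfkit import evaluate as ev, simulate as sim
from nsfkit.factor_models import FitConfig, SpatialFactorModel
from nsfkit.preprocess import split_train_validation

data, truth = sim.simulate_scenario2("quilt", "split", n_features=500, seed=1)
train, val = split_train_validation(data.n_obs, 0.05, seed=1)

model = SpatialFactorModel.from_dataset(data.subset(train), family="nsfh", L=7, T=4)
results = model.fit(FitConfig(seed=1, max_iter=300))
print(results.summary())
```

```
SpatialFactorModel results
========================================
family:            NSFH
likelihood:        poi
components (L/T):  7/4
observations (N):  1231
features (J):      500
inducing points:   1231 (all)
kernel:            matern32 (lengthscale 0.1 of domain)
iterations run:    300
converged at:      not converged
final objective:   798612.2913
```

```python
rec = ev.benchmark_fit(results, data, train, val, seed=1)
scores = results.gene_spatial_scores()
print(f"validation deviance:     {rec.validation_deviance:.1f}")
print(f"mean fitted gene score:  {scores.mean():.3f}")
print(f"mean true gene score:    {truth.true_gene_scores.mean():.3f}")
print(f"score recovery distance: "
      f"{ev.score_recovery_distance(scores, truth.true_gene_scores):.2f}")
```

```
validation deviance:     3400.9
mean fitted gene score:  0.501
mean true gene score:    0.500
score recovery distance: 0.20
```

The fitted scores identify which genes are spatial: a pure spatial model
(`nsf`, scores identically 1) or pure nonspatial model (`pnmf`, scores
identically 0) has a score recovery distance of 15.8 on the same data.

On a scenario-I replicate (every gene spatial, one-hot loadings on four
quilt patterns, 200 genes, same split and a 300-iteration budget), the four
non-hybrid families give:

| family | validation deviance | min matched factor corr. |
|--------|--------------------:|-------------------------:|
| `nsf`  |               348.5 | 0.997 |
| `pnmf` |              2705.8 | 0.997 |
| `rsf`  |               332.2 | 0.681 |
| `fa`   |              3333.0 | 0.674 |

Spatial models generalize far better than their nonspatial counterparts
within each likelihood, and the nonnegative count models recover the true
factors nearly perfectly while the real-valued models mix them (their
factors are identifiable only up to rotation).

## Command line

```bash
nsfkit simulate --pattern quilt --scenario 2 --mode split --seed 1 --out ds/
nsfkit fit ds/ --model nsfh -L 7 --t-spatial 4 --out res/
nsfkit postprocess res/ --style spde
nsfkit benchmark ds/ --families pnmf,nsf --out bench.csv
nsfkit evaluate ds/ res/ --out eval.json
```

Datasets are read from text bundles (Matrix Market counts + TSV
coordinates) or `.h5ad` files with coordinates in `obsm['spatial']`.

## Reproduction

```bash
python -m pytest -q tests/                     # full suite, ~5 min on 1 CPU
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per headline claim (generator
constants, score limiting cases, oracle equivalences, reduced-budget
parameter recovery, convergence detection). `scripts/acceptance.py`
recomputes the quantitative acceptance targets from scratch for any seed.
All numbers in this README were produced by the code above with the seeds
shown.

See `docs/methods.md` for model definitions, default hyperparameters and
their rationale, simulation design, and known limitations.

## Reference

Townes, F.W. & Engelhardt, B.E. Nonnegative spatial factorization applied
to spatial genomics. *Nature Methods* 20, 229–238 (2023).
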