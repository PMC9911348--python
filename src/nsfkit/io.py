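"""Reading and writing datasets, fits and result bundles.

On-disk dataset formats: a directory bundle (Matrix Market counts +
TSV coordinate/feature tables + JSON metadata) or an H5AD container with
coordinates in ``obsm['spatial']``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import CountDataset, SimulationTruth
from .exceptions import InvalidArgumentError

COUNTS_FILE = "counts.mtx"
COORDS_FILE = "coords.tsv"
FEATURES_FILE = "features.tsv"
META_FILE = "metadata.json"


def write_dataset(dataset: CountDataset, out_dir, truth: SimulationTruth | None = None,
                  metadata: dict | None = None) -> Path:
    """Write a dataset (and optional simulation truth) as a text bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / COUNTS_FILE, sp.csr_matrix(dataset.counts().astype(int)))
    pd.DataFrame(dataset.X, columns=[f"dim{d}" for d in range(dataset.X.shape[1])]).to_csv(
        out / COORDS_FILE, sep="\t", index=False)
    pd.DataFrame({"feature_id": dataset.feature_ids, "size_factor_weight": 1.0}).to_csv(
        out / FEATURES_FILE, sep="\t", index=False)
    meta = dict(metadata or {})
    meta.setdefault("n_obs", int(dataset.n_obs))
    meta.setdefault("n_features", int(dataset.n_features))
    if truth is not None:
        for name, mat in (("truth_F", truth.F), ("truth_H", truth.H),
                          ("truth_W", truth.W), ("truth_V", truth.V)):
            pd.DataFrame(mat).to_csv(out / f"{name}.csv", index=False)
        pd.DataFrame({"true_gene_score": truth.true_gene_scores}).to_csv(
            out / "truth_gene_scores.csv", index=False)
        meta["seed"] = int(truth.seed)
    (out / META_FILE).write_text(json.dumps(meta, indent=2))
    return out


def read_dataset(path) -> CountDataset:
    """Read a dataset from a bundle directory or an .h5ad file.

    Counts must be (coercible to) nonnegative integers; coordinates are
    required. Duplicate coordinate rows are allowed.
    """
    path = Path(path)
    if path.suffix == ".h5ad":
        return _read_h5ad(path)
    if not path.is_dir():
        raise InvalidArgumentError(f"{path} is neither a bundle directory nor an .h5ad file")
    counts_path = path / COUNTS_FILE
    coords_path = path / COORDS_FILE
    if not counts_path.exists():
        raise InvalidArgumentError(f"missing {COUNTS_FILE} in {path}")
    if not coords_path.exists():
        raise InvalidArgumentError(
            f"missing {COORDS_FILE} in {path}: spatial coordinates are required")
    Y = sp.csr_matrix(mmread(counts_path))
    _validate_integer_counts(Y)
    X = pd.read_csv(coords_path, sep="\t").to_numpy(dtype=float)
    feature_ids = None
    fpath = path / FEATURES_FILE
    if fpath.exists():
        feature_ids = pd.read_csv(fpath, sep="\t")["feature_id"].to_numpy()
    return CountDataset(Y=Y, X=X, feature_ids=feature_ids)


def _validate_integer_counts(Y):
    data = Y.data if sp.issparse(Y) else np.asarray(Y)
    if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
        raise InvalidArgumentError(
            "counts must be nonnegative integers; if the matrix holds normalized "
            "values, supply the raw counts layer instead")


def _read_h5ad(path: Path) -> CountDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    X = adata.obsm.get("spatial")
    if X is None:
        raise InvalidArgumentError(
            f"{path} has no obsm['spatial'] slot; spatial coordinates are required")
    Y = adata.layers.get("counts", adata.X)
    if sp.issparse(Y):
        Y = sp.csr_matrix(Y)
    else:
        Y = np.asarray(Y)
    _validate_integer_counts(Y)
    return CountDataset(Y=Y, X=np.asarray(X, dtype=float),
                        feature_ids=adata.var_names.to_numpy())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(results, out_dir, metrics: dict | None = None,
                  config: dict | None = None) -> dict:
    """Write fitted factors/loadings, scores, metrics and a hash manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = results.model
    F, H = results.factors()
    pd.DataFrame(np.hstack([F, H])).to_csv(out / "factors.csv", index=False)
    pd.DataFrame(results.loadings, index=m.feature_ids).to_csv(out / "loadings.csv")
    if m.nonneg:
        proj = results.simplex("spde")
        pd.DataFrame({"w_bar": proj.scale}).to_csv(out / "w_bar.csv", index=False)
        if 0 < m.T < m.L:
            pd.DataFrame({"gene_score": results.gene_spatial_scores()}).to_csv(
                out / "gene_scores.csv", index=False)
            pd.DataFrame({"observation_score": results.observation_spatial_scores()}).to_csv(
                out / "observation_scores.csv", index=False)
    trace = results.trace
    pd.DataFrame({
        "iteration": trace.iterations,
        "objective": trace.objective,
        "smoothed": [trace.smoothed.get(i, np.nan) for i in trace.iterations],
    }).to_csv(out / "trace.csv", index=False)
    (out / "summary.txt").write_text(results.summary() + "\n")
    if metrics is not None:
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))
    if config is not None:
        (out / "config.json").write_text(json.dumps(config, indent=2, default=str))
    manifest = {
        "artifacts": {
            p.name: _sha256(p) for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
        "absent": [],
    }
    if not (out / "gene_scores.csv").exists():
        manifest["absent"].append("gene_scores.csv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
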