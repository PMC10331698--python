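"""Self-organizing-map clustering of response profiles.

A rectangular grid of codebook vectors is trained with the batch SOM
algorithm: every epoch assigns each profile to its best-matching unit (BMU,
nearest codebook by unweighted Euclidean distance over all endpoints) and
replaces each codebook with the Gaussian-neighborhood-weighted mean of the
profiles, with the neighborhood radius decaying linearly from max(grid)/2
to 1.  Codebooks are initialized deterministically on the plane of the first
two principal components, so training is reproducible for a given seed and
input (the seed only matters for the optional random initialization).

Cluster ids are numbered from the lower-left node to the top-right node:
node at row *r* (from the bottom) and column *c* (from the left) has id
``r·cols + c + 1``.

The profiling workflow is two-pass: the full profile set is clustered on a
7×7 grid, then profiles with more than two positive cytotoxicity endpoints
are removed and the remainder re-clustered on a 6×6 grid, since broad
cytotoxic suppression otherwise dominates the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .cytotox import filter_for_profiling
from .io import ProfileMatrix


@dataclass
class SOMModel:
    grid_rows: int
    grid_cols: int
    codebook: np.ndarray          # (rows*cols, n_endpoints); node r*cols+c
    endpoints: list[str]
    qe_history: list[float] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols

    def node_id(self, row_from_bottom: int, col_from_left: int) -> int:
        """Cluster id of a grid node (1-based, lower-left to top-right)."""
        return row_from_bottom * self.grid_cols + col_from_left + 1

    def codebook_frame(self) -> pd.DataFrame:
        ids = np.arange(1, self.n_nodes + 1)
        return pd.DataFrame(self.codebook, index=pd.Index(ids, name="cluster"),
                            columns=self.endpoints)


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    """(n_nodes, 2) array of (row, col) grid positions, node index r*cols+c."""
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _pca_init(X: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Codebooks spanning ±2 sd on the first two principal components."""
    mean = X.mean(axis=0)
    Xc = X - mean
    # deterministic SVD sign convention: dominant loading positive
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(min(2, vt.shape[0])):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
    sd = s / max(np.sqrt(X.shape[0] - 1.0), 1.0)
    coords = _grid_coords(rows, cols)
    u_row = (2.0 * coords[:, 0] / max(rows - 1, 1)) - 1.0  # -1..1 bottom→top
    u_col = (2.0 * coords[:, 1] / max(cols - 1, 1)) - 1.0
    code = np.tile(mean, (rows * cols, 1))
    if len(s) >= 1 and sd[0] > 0:
        code += 2.0 * sd[0] * u_col[:, None] * vt[0]
    if len(s) >= 2 and sd[1] > 0:
        code += 2.0 * sd[1] * u_row[:, None] * vt[1]
    return code


def train_som(profiles: ProfileMatrix, grid: tuple[int, int],
              epochs: int = 100, seed: int = 0,
              init: str = "pca", radius_end: float = 1.0) -> SOMModel:
    """Train a batch SOM on the profile rows.

    ``init`` is ``"pca"`` (deterministic principal-component plane, default)
    or ``"random"`` (profiles sampled with the seed).  The neighborhood
    radius decays linearly from ``max(grid)/2`` to ``radius_end``.
    """
    X = profiles.values.to_numpy(float)
    if X.shape[0] == 0:
        raise ValueError("cannot train a SOM on an empty profile set")
    rows, cols = grid
    n_nodes = rows * cols
    if X.shape[0] < n_nodes:
        warnings.warn(
            f"{X.shape[0]} profiles for {n_nodes} SOM nodes; "
            "map may be underpopulated", stacklevel=2)

    rng = np.random.default_rng(seed)
    if init == "pca":
        codebook = _pca_init(X, rows, cols)
    elif init == "random":
        codebook = X[rng.integers(0, X.shape[0], size=n_nodes)].copy()
    else:
        raise ValueError(f"unknown init {init!r}")

    coords = _grid_coords(rows, cols)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    radius0 = max(rows, cols) / 2.0

    qe_history: list[float] = []
    for t in range(epochs):
        frac = t / max(epochs - 1, 1)
        sigma = radius0 + (radius_end - radius0) * frac
        d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        bmu = d2.argmin(axis=1)
        h = np.exp(-grid_d2 / (2.0 * sigma ** 2))       # (nodes, nodes)
        w = h[:, bmu]                                   # (nodes, samples)
        denom = w.sum(axis=1)
        codebook = (w @ X) / denom[:, None]
        d2_new = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        qe_history.append(float(np.sqrt(d2_new.min(axis=1)).mean()))

    return SOMModel(
        rows, cols, codebook, list(profiles.values.columns), qe_history,
        params={"epochs": epochs, "init": init,
                "radius0": radius0, "radius_end": radius_end},
        seed=seed,
    )


def assign_clusters(model: SOMModel, profiles: ProfileMatrix) -> pd.Series:
    """Assign each profile row to its nearest codebook's cluster id."""
    if list(profiles.values.columns) != model.endpoints:
        raise ValueError("profile endpoints do not match the trained SOM")
    X = profiles.values.to_numpy(float)
    d2 = ((X[:, None, :] - model.codebook[None, :, :]) ** 2).sum(axis=2)
    return pd.Series(d2.argmin(axis=1) + 1, index=profiles.values.index,
                     name="cluster")


def quantization_error(model: SOMModel, profiles: ProfileMatrix) -> float:
    """Mean Euclidean distance of profiles to their assigned codebooks."""
    X = profiles.values.to_numpy(float)
    d2 = ((X[:, None, :] - model.codebook[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


@dataclass
class TwoPassClustering:
    som_full: SOMModel
    som_filtered: SOMModel
    assignments_full: pd.Series
    assignments_filtered: pd.Series
    cluster_summary: pd.DataFrame   # filtered map: per-cluster membership


def two_pass_clustering(profiles: ProfileMatrix, cytotox_counts: pd.Series,
                        config: PipelineConfig | None = None
                        ) -> TwoPassClustering:
    """Full-set SOM (7×7), then cytotoxicity-filtered SOM (6×6).

    ``cytotox_counts`` gives the positive-cytotoxicity-endpoint count per
    (sample, concentration) row; rows exceeding the configured maximum are
    removed before the second pass.
    """
    config = config or PipelineConfig()
    som_full = train_som(profiles, config.som_full_grid,
                         epochs=config.som_epochs, seed=config.seed)
    assign_full = assign_clusters(som_full, profiles)

    filtered = filter_for_profiling(
        profiles, cytotox_counts, config.max_cytotox_endpoints_for_profiling)
    som_filt = train_som(filtered, config.som_filtered_grid,
                         epochs=config.som_epochs, seed=config.seed)
    assign_filt = assign_clusters(som_filt, filtered)

    summary = (
        pd.DataFrame({
            "cluster": assign_filt,
            "n_cytotox": cytotox_counts.reindex(filtered.values.index),
            "chemical_id": [
                filtered.chemical_of(s)
                for s in filtered.values.index.get_level_values("sample_id")
            ],
        })
        .groupby("cluster")
        .agg(
            n_profiles=("chemical_id", "size"),
            mean_cytotox=("n_cytotox", "mean"),
            chemicals=("chemical_id", lambda s: ";".join(sorted(set(s)))),
        )
        .reset_index()
    )
    return TwoPassClustering(som_full, som_filt, assign_full, assign_filt, summary)
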