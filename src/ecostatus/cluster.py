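"""Ecological-status definition by tuned hierarchical clustering.

The 25-feature matrix per ocean cell (5 dominant-taxon abundances, Shannon
index, 19 pathway abundances; richness excluded) is z-scored, reduced by PCA
to the components carrying >= 95% of variance, and clustered agglomeratively.
The (k, linkage, metric) configuration is chosen by silhouette score computed
in the same PCA space; status labels are renumbered canonically (descending
cluster size, ties by descending mean Cyanobacteria abundance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .constants import STATUS_FEATURES
from .stats import PCAResult, pca_reduce

__all__ = [
    "StatusFeatureMatrix",
    "ClusterTuningResult",
    "EcoStatusLabeling",
    "build_feature_matrix",
    "tune_hierarchical",
    "assign_status",
    "profile_status",
]

DEFAULT_K_RANGE = tuple(range(2, 13))
DEFAULT_LINKAGES = ("ward", "complete", "average")
DEFAULT_METRICS = ("euclidean", "cityblock", "cosine")


@dataclass
class StatusFeatureMatrix:
    """Raw, standardized and PCA-reduced views of the per-cell features."""

    raw: pd.DataFrame            # (n_cells, 25), index = (lat, lon) or ids
    standardized: np.ndarray     # (n_cells, 25)
    pca: PCAResult               # fitted on the standardized copy

    @property
    def reduced(self) -> np.ndarray:
        return self.pca.scores

    def __len__(self) -> int:
        return len(self.raw)


def build_feature_matrix(index_grid: xr.Dataset | pd.DataFrame,
                         var_frac: float = 0.95,
                         standardize: bool = True) -> StatusFeatureMatrix:
    """Assemble the 25-column status feature matrix from an index grid or an
    index table; masked (NaN) cells are dropped."""
    if isinstance(index_grid, xr.Dataset):
        missing = [n for n in STATUS_FEATURES if n not in index_grid.data_vars]
        if missing:
            raise ValueError(f"missing index variable(s): {missing}")
        df = index_grid[list(STATUS_FEATURES)].to_dataframe()[list(STATUS_FEATURES)]
    else:
        missing = [n for n in STATUS_FEATURES if n not in index_grid.columns]
        if missing:
            raise ValueError(f"missing index column(s): {missing}")
        df = index_grid[list(STATUS_FEATURES)]
    df = df.dropna()
    if df.empty:
        raise ValueError("no unmasked cells: feature matrix is empty")
    pca = pca_reduce(df.to_numpy(), var_frac=var_frac, standardize=standardize)
    z = pca._scaler.transform(df.to_numpy()) if pca._scaler is not None else df.to_numpy()
    return StatusFeatureMatrix(raw=df, standardized=z, pca=pca)


@dataclass
class ClusterTuningResult:
    """Silhouette over the whole (k, linkage, metric) grid plus the argmax."""

    records: pd.DataFrame  # columns k, linkage, metric, silhouette
    best_k: int
    best_linkage: str
    best_metric: str
    best_silhouette: float


def _cluster(X: np.ndarray, k: int, linkage: str, metric: str) -> np.ndarray:
    model = AgglomerativeClustering(n_clusters=k, linkage=linkage, metric=metric)
    return model.fit_predict(X)


def tune_hierarchical(features: StatusFeatureMatrix,
                      k_range=DEFAULT_K_RANGE,
                      linkages=DEFAULT_LINKAGES,
                      metrics=DEFAULT_METRICS) -> ClusterTuningResult:
    """Evaluate silhouette for every valid configuration and pick the best.

    Ward is only valid with Euclidean distance; invalid combinations are
    skipped. Ties prefer smaller k, then the configuration order given.
    """
    X = features.reduced
    n = len(X)
    rows = []
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        for linkage in linkages:
            for metric in metrics:
                if linkage == "ward" and metric != "euclidean":
                    continue
                labels = _cluster(X, k, linkage, metric)
                if len(np.unique(labels)) < 2:
                    continue
                sil = silhouette_score(X, labels, metric=metric)
                rows.append({"k": k, "linkage": linkage, "metric": metric,
                             "silhouette": sil})
    if not rows:
        raise ValueError("no valid clustering configuration to evaluate")
    rec = pd.DataFrame(rows)
    # stable argmax: best silhouette, ties -> smallest k, then listed order
    order = rec.sort_values(["silhouette", "k"], ascending=[False, True],
                            kind="stable")
    best = order.iloc[0]
    return ClusterTuningResult(
        records=rec,
        best_k=int(best["k"]),
        best_linkage=str(best["linkage"]),
        best_metric=str(best["metric"]),
        best_silhouette=float(best["silhouette"]),
    )


@dataclass
class EcoStatusLabeling:
    """Status label per cell (1..K) plus centroids for out-of-sample use."""

    labels: pd.Series            # int, aligned to feature-matrix index
    k: int
    linkage: str
    metric: str
    centroids: np.ndarray        # (K, m) in the PCA space, row i = status i+1
    pca: PCAResult

    def assign_new(self, features_raw: np.ndarray) -> np.ndarray:
        """Nearest-centroid status (1..K) for new 25-feature rows."""
        scores = self.pca.transform(np.asarray(features_raw, dtype=float))
        d = np.linalg.norm(scores[:, None, :] - self.centroids[None], axis=-1)
        return d.argmin(axis=1) + 1

    def to_grid(self, template: xr.DataArray) -> xr.DataArray:
        """Scatter labels onto a lat/lon grid shaped like ``template``."""
        arr = np.full(template.shape, np.nan)
        lat_index = pd.Index(template["lat"].values)
        lon_index = pd.Index(template["lon"].values)
        lats = self.labels.index.get_level_values("lat")
        lons = self.labels.index.get_level_values("lon")
        arr[lat_index.get_indexer(lats), lon_index.get_indexer(lons)] = (
            self.labels.to_numpy(dtype=float)
        )
        return xr.DataArray(arr, coords={"lat": template["lat"].values,
                                         "lon": template["lon"].values},
                            dims=("lat", "lon"), name="status")


def _canonical_relabel(raw_labels: np.ndarray, cyano: np.ndarray) -> np.ndarray:
    """Renumber clusters 1..K by descending size; ties by descending mean
    Cyanobacteria abundance."""
    uniq = np.unique(raw_labels)
    sizes = {g: np.sum(raw_labels == g) for g in uniq}
    means = {g: cyano[raw_labels == g].mean() for g in uniq}
    ordered = sorted(uniq, key=lambda g: (-sizes[g], -means[g]))
    mapping = {g: i + 1 for i, g in enumerate(ordered)}
    return np.array([mapping[g] for g in raw_labels])


def assign_status(features: StatusFeatureMatrix, k: int,
                  linkage: str = "ward", metric: str = "euclidean") -> EcoStatusLabeling:
    """Cluster the reduced features into k statuses with canonical labels."""
    n = len(features)
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} cells")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the Euclidean metric")
    X = features.reduced
    raw = _cluster(X, k, linkage, metric) if k > 1 else np.zeros(n, dtype=int)
    cyano = features.raw["Cyanobacteria"].to_numpy()
    labels = _canonical_relabel(raw, cyano)
    centroids = np.vstack([X[labels == i + 1].mean(axis=0) for i in range(k)])
    return EcoStatusLabeling(
        labels=pd.Series(labels, index=features.raw.index, name="status"),
        k=k, linkage=linkage, metric=metric, centroids=centroids,
        pca=features.pca,
    )


def profile_status(labeling: EcoStatusLabeling,
                   index_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-status medians of every index and across-status z-scores.

    ``index_table`` rows must align with the labeling's cells. Returns
    ``{"median": K x indices, "zscore": K x indices}`` where z-scores are
    computed across statuses within each column (population sd). Empty status
    classes are excluded with a warning; with a single status all z-scores
    are 0.
    """
    common = labeling.labels.index.intersection(index_table.index)
    if len(common) == 0:
        raise ValueError("labels do not align with the index table")
    labels = labeling.labels.loc[common]
    table = index_table.loc[common]
    present = sorted(labels.unique())
    if len(present) < labeling.k:
        warnings.warn("empty status class(es) excluded from the profile")
    med = table.groupby(labels).median()
    med.index.name = "status"
    sd = med.std(axis=0, ddof=0)
    centered = med - med.mean(axis=0)
    z = centered.div(sd.where(sd > 0, 1.0), axis=1)
    z[sd.index[sd == 0]] = 0.0
    return {"median": med, "zscore": z}
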