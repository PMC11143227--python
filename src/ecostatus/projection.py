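"""Scenario projection: status maps, change maps and area summaries.

Applies the fitted status classifier to a present and a future environmental
grid, flags the cells whose predicted status differs ("changed area"), and
summarizes changed-area fractions, per-status composition, the status
transition table, and per-index change fields with latitudinal band means.
Area weighting defaults to plain cell counts (the grid-point proportion);
cosine-latitude weighting is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .models import ClassifierBundle, RegressionBundle, predict_indices, predict_status_proba

__all__ = [
    "ChangeMap",
    "AreaSummary",
    "project_scenario",
    "changed_fraction",
    "status_composition",
    "index_change_summary",
    "render_map",
]

WEIGHTINGS = ("cell_count", "cos_latitude")


def render_map(da: xr.DataArray, path, cmap: str = "viridis",
               title: str | None = None) -> None:
    """Quick PNG world map of a gridded field (land/NaN left blank)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    lats, lons = da["lat"].values, da["lon"].values
    im = ax.pcolormesh(lons, lats, da.values, cmap=cmap, shading="auto")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _cell_weights(da: xr.DataArray, weighting: str) -> xr.DataArray:
    if weighting == "cell_count":
        return xr.ones_like(da)
    if weighting == "cos_latitude":
        w = np.cos(np.deg2rad(da["lat"]))
        return xr.ones_like(da) * w
    raise ValueError(f"unknown weighting: {weighting!r}")


@dataclass
class ChangeMap:
    """Present/future status grids, the changed-cell mask, and the underlying
    probability fields. ``n_mask_mismatch`` counts cells that are ocean in one
    scenario but masked in the other; they are excluded everywhere."""

    status_present: xr.DataArray
    status_future: xr.DataArray
    changed: xr.DataArray          # 1.0 changed, 0.0 unchanged, NaN masked
    probs_present: xr.Dataset
    probs_future: xr.Dataset
    classes: np.ndarray
    n_mask_mismatch: int = 0


def project_scenario(classifier: ClassifierBundle, env_present: xr.Dataset,
                     env_future: xr.Dataset) -> ChangeMap:
    """Predict status under both scenarios and flag changed cells."""
    for c in ("lat", "lon"):
        if not np.array_equal(env_present[c].values, env_future[c].values):
            raise ValueError("present and future grids do not share coordinates")
    probs_p, status_p = predict_status_proba(classifier, env_present)
    probs_f, status_f = predict_status_proba(classifier, env_future)

    ocean_p = status_p.notnull()
    ocean_f = status_f.notnull()
    common = ocean_p & ocean_f
    mismatch = int((ocean_p ^ ocean_f).sum())
    status_p = status_p.where(common)
    status_f = status_f.where(common)
    probs_p = probs_p.where(common)
    probs_f = probs_f.where(common)
    changed = xr.where(common, (status_p != status_f).astype(float), np.nan)
    return ChangeMap(
        status_present=status_p, status_future=status_f, changed=changed,
        probs_present=probs_p, probs_future=probs_f,
        classes=classifier.classes, n_mask_mismatch=mismatch,
    )


def changed_fraction(change_map: ChangeMap, weighting: str = "cell_count") -> float:
    """Changed share of the ocean, in percent of (weighted) ocean cells."""
    changed = change_map.changed
    ocean = changed.notnull()
    n_ocean = int(ocean.sum())
    if n_ocean == 0:
        raise ValueError("no ocean cells in the change map")
    w = _cell_weights(changed, weighting).where(ocean)
    total = float(w.sum())
    hit = float(w.where(changed == 1.0).sum())
    return 100.0 * hit / total


@dataclass
class AreaSummary:
    """Per-status ocean-area composition (percent) and the transition table
    of changed cells (weighted counts, rows=present status, cols=future)."""

    fraction_changed: float
    composition_present: pd.Series
    composition_future: pd.Series
    transition: pd.DataFrame
    weighting: str


def status_composition(change_map: ChangeMap,
                       weighting: str = "cell_count") -> AreaSummary:
    classes = [int(c) for c in change_map.classes]
    ocean = change_map.changed.notnull()
    w = _cell_weights(change_map.changed, weighting).where(ocean)
    total = float(w.sum())
    if total == 0:
        raise ValueError("no ocean cells in the change map")

    def comp(status: xr.DataArray) -> pd.Series:
        shares = {c: 100.0 * float(w.where(status == c).sum()) / total
                  for c in classes}
        return pd.Series(shares, name="percent")

    trans = pd.DataFrame(0.0, index=pd.Index(classes, name="present"),
                         columns=pd.Index(classes, name="future"))
    changed = change_map.changed == 1.0
    for a in classes:
        from_a = changed & (change_map.status_present == a)
        for b in classes:
            if a == b:
                continue
            sel = from_a & (change_map.status_future == b)
            trans.loc[a, b] = float(w.where(sel).sum())
    return AreaSummary(
        fraction_changed=100.0 * float(trans.to_numpy().sum()) / total,
        composition_present=comp(change_map.status_present),
        composition_future=comp(change_map.status_future),
        transition=trans,
        weighting=weighting,
    )


def index_change_summary(regressors: RegressionBundle, env_present: xr.Dataset,
                         env_future: xr.Dataset,
                         changed_mask: xr.DataArray | None = None,
                         band_width: float = 10.0,
                         changed_only: bool = True) -> dict:
    """Future-minus-present change per retained index.

    Returns ``delta`` (per-index change fields, restricted to changed cells
    when ``changed_only``), ``band_means`` (mean delta per latitude band,
    half-open [lo, hi) bins of ``band_width`` degrees), and ``pct_increase``
    (percent of considered cells where each index increases).
    """
    pred_p = predict_indices(regressors, env_present)
    pred_f = predict_indices(regressors, env_future)
    delta = pred_f - pred_p
    if changed_only:
        if changed_mask is None:
            raise ValueError("changed_only=True requires a changed_mask")
        delta = delta.where(changed_mask == 1.0)

    names = list(delta.data_vars)
    any_cells = any(int(delta[n].notnull().sum()) > 0 for n in names)
    if not any_cells:
        warnings.warn("no cells in scope: index change summaries are empty")
        return {"delta": delta,
                "band_means": pd.DataFrame(columns=names),
                "pct_increase": pd.Series(dtype=float)}

    lats = delta["lat"].values
    lo = np.floor(lats.min() / band_width) * band_width
    hi = np.ceil(lats.max() / band_width) * band_width
    edges = np.arange(lo, hi + band_width, band_width)
    band_ids = np.digitize(lats, edges[1:], right=False)  # [lo, hi) bins
    labels = [f"[{edges[i]:g}, {edges[i + 1]:g})" for i in range(len(edges) - 1)]

    band_rows = {}
    pct = {}
    for n in names:
        arr = delta[n].values
        means = []
        for b in range(len(edges) - 1):
            block = arr[band_ids == b]
            means.append(np.nanmean(block) if np.isfinite(block).any() else np.nan)
        band_rows[n] = means
        finite = arr[np.isfinite(arr)]
        pct[n] = 100.0 * float((finite > 0).mean()) if len(finite) else np.nan
    band_means = pd.DataFrame(band_rows, index=pd.Index(labels, name="lat_band"))
    return {"delta": delta, "band_means": band_means,
            "pct_increase": pd.Series(pct, name="pct_of_cells_increasing")}
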