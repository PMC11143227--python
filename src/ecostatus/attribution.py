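"""One-factor-at-a-time counterfactual attribution of status change.

For each grid cell, the classifier's status probabilities are computed once
under the present environment and then ten more times, each with a single
factor set to its future value. The relative contribution of factor e is

    RC_e = sum_n |P_n(future e only) - P_n(present)|
           / sum_e' sum_n |P_n(future e' only) - P_n(present)|

so contributions are non-negative and sum to 1 on cells where any swap moves
the probabilities at all; cells with a zero denominator are flagged
non-attributable. The dominant driver of a cell is the factor with the
highest RC (ties broken by the canonical factor order). Scope defaults to the
changed-area mask, since unchanged regions are excluded from this analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .constants import FACTORS, NUTRIENT_FACTORS
from .models import ClassifierBundle

__all__ = ["AttributionGrid", "relative_contributions", "dominant_driver"]

DEFAULT_FACTOR_GROUPS: dict[str, tuple[str, ...]] = {
    "nutrients": NUTRIENT_FACTORS,
    "other": tuple(f for f in FACTORS if f not in NUTRIENT_FACTORS),
}


@dataclass
class AttributionGrid:
    """Per-factor relative contributions on the attribution scope.

    ``rc``: Dataset with one variable per factor, NaN off-scope.
    ``attributable``: 1.0 where the denominator was positive, 0.0 where every
    single-factor swap left the probabilities untouched, NaN off-scope.
    """

    rc: xr.Dataset
    attributable: xr.DataArray
    factor_groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_GROUPS)
    )


def relative_contributions(classifier: ClassifierBundle,
                           env_present: xr.Dataset, env_future: xr.Dataset,
                           scope: xr.DataArray | None = None) -> AttributionGrid:
    """Counterfactual RC per factor on the in-scope ocean cells.

    ``scope`` is a 0/1 (or boolean) cell mask, typically the changed-area
    mask from a ChangeMap; ``None`` means all common ocean cells.
    """
    for c in ("lat", "lon"):
        if not np.array_equal(env_present[c].values, env_future[c].values):
            raise ValueError("present and future grids do not share coordinates")
    missing = [f for f in FACTORS
               if f not in env_present.data_vars or f not in env_future.data_vars]
    if missing:
        raise ValueError(f"missing factor(s): {missing}")

    frame_p = env_present[list(FACTORS)].to_dataframe()[list(FACTORS)].dropna()
    frame_f = env_future[list(FACTORS)].to_dataframe()[list(FACTORS)].dropna()
    common = frame_p.index.intersection(frame_f.index)
    frame_p, frame_f = frame_p.loc[common], frame_f.loc[common]

    if scope is not None:
        in_scope = scope.to_series().reindex(common).fillna(0.0).astype(bool)
        frame_p, frame_f = frame_p[in_scope.values], frame_f[in_scope.values]
    if frame_p.empty:
        warnings.warn("attribution scope is empty")

    proba_present = classifier.model.predict_proba(frame_p.to_numpy())
    numerators = np.zeros((len(frame_p), len(FACTORS)))
    for j, f in enumerate(FACTORS):
        swapped = frame_p.copy()
        swapped[f] = frame_f[f]
        proba_e = classifier.model.predict_proba(swapped.to_numpy())
        numerators[:, j] = np.abs(proba_e - proba_present).sum(axis=1)
    denom = numerators.sum(axis=1)
    attributable = denom > 0
    rc = np.full_like(numerators, np.nan)
    rc[attributable] = numerators[attributable] / denom[attributable, None]
    rc[~attributable] = 0.0

    template = env_present[FACTORS[0]]
    lat_index = pd.Index(template["lat"].values)
    lon_index = pd.Index(template["lon"].values)
    ii = lat_index.get_indexer(frame_p.index.get_level_values("lat"))
    jj = lon_index.get_indexer(frame_p.index.get_level_values("lon"))
    data = {}
    for j, f in enumerate(FACTORS):
        arr = np.full(template.shape, np.nan)
        arr[ii, jj] = rc[:, j]
        data[f] = xr.DataArray(arr, coords={"lat": lat_index.values,
                                            "lon": lon_index.values},
                               dims=("lat", "lon"), name=f)
    arr = np.full(template.shape, np.nan)
    arr[ii, jj] = attributable.astype(float)
    attr_da = xr.DataArray(arr, coords={"lat": lat_index.values,
                                        "lon": lon_index.values},
                           dims=("lat", "lon"), name="attributable")
    return AttributionGrid(rc=xr.Dataset(data), attributable=attr_da)


def dominant_driver(attr: AttributionGrid) -> dict:
    """Dominant factor per cell and area shares.

    Returns ``dominant`` (DataArray of factor codes in canonical order, NaN
    where non-attributable or off-scope), ``factor_share`` (percent of
    attributable cells dominated by each factor), and ``group_share``
    (percent per factor group, e.g. nutrients vs. other).
    """
    stack = np.stack([attr.rc[f].values for f in FACTORS])  # (10, lat, lon)
    ok = (attr.attributable == 1.0).values
    if not ok.any():
        warnings.warn("no attributable cells: dominant-driver summary empty")
        empty = pd.Series(dtype=float)
        dom = xr.full_like(attr.attributable, np.nan).rename("dominant")
        return {"dominant": dom, "factor_share": empty, "group_share": empty}

    # np.argmax takes the first maximum -> canonical factor order tie-break
    codes = np.argmax(np.nan_to_num(stack, nan=-np.inf), axis=0).astype(float)
    codes[~ok] = np.nan
    dom = xr.DataArray(codes, coords=attr.attributable.coords,
                       dims=attr.attributable.dims, name="dominant")
    dom.attrs["factor_order"] = ",".join(FACTORS)

    flat = codes[ok].astype(int)
    counts = np.bincount(flat, minlength=len(FACTORS))
    share = pd.Series(100.0 * counts / counts.sum(), index=list(FACTORS),
                      name="percent_of_attributable_area")
    group = pd.Series(
        {g: float(share[list(members)].sum())
         for g, members in attr.factor_groups.items()},
        name="percent_of_attributable_area",
    )
    return {"dominant": dom, "factor_share": share, "group_share": group}
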