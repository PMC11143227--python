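"""Shared fixtures: small synthetic grids, truth mappings, toy classifiers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import ecostatus as es
from ecostatus.constants import FACTOR_RANGES, FACTORS
from ecostatus.models import ClassifierBundle


def toy_env_grid(values: dict[str, np.ndarray], lats, lons) -> xr.Dataset:
    """Small environmental grid; unspecified factors sit at mid-range."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    shape = (len(lats), len(lons))
    data = {}
    for f in FACTORS:
        if f in values:
            arr = np.broadcast_to(np.asarray(values[f], dtype=float), shape).copy()
        else:
            lo, hi = FACTOR_RANGES[f]
            arr = np.full(shape, (lo + hi) / 2)
        data[f] = xr.DataArray(arr, coords={"lat": lats, "lon": lons},
                               dims=("lat", "lon"))
    return xr.Dataset(data)


class SoftmaxModel:
    """Analytic probabilistic classifier: softmax(X @ W + b)."""

    def __init__(self, W: np.ndarray, b: np.ndarray):
        self.W = np.asarray(W, dtype=float)
        self.b = np.asarray(b, dtype=float)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = np.asarray(X, dtype=float) @ self.W + self.b
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def toy_classifier(W: np.ndarray, b: np.ndarray) -> ClassifierBundle:
    k = W.shape[1]
    return ClassifierBundle(
        model=SoftmaxModel(W, b), family="toy", params={},
        classes=np.arange(1, k + 1), cv_accuracy=np.nan,
        train_accuracy=np.nan, test_accuracy=None, confusion=None,
        importance=pd.Series(np.full(len(FACTORS), 0.1), index=list(FACTORS)),
        seed=0,
    )


@pytest.fixture(scope="session")
def ocean_system():
    """Masked 40x90-cell world (~2700 ocean cells): env grid, truth mapping,
    index grid and latent status labels."""
    spec = es.GridSpec(4.0, 4.0)
    spec = es.GridSpec(4.0, 4.0,
                       ocean_mask=es.random_ocean_mask(spec, 0.25, seed=3))
    env = es.gen_env_grid(spec, seed=5)
    truth = es.make_truth_mapping(env, n_status=7, seed=7)
    index_grid, latent = es.gen_index_fields(env, truth)
    return {"spec": spec, "env": env, "truth": truth,
            "index_grid": index_grid, "latent": latent}


@pytest.fixture(scope="session")
def catalog():
    return es.gen_gene_catalog(19, 3, seed=1)
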