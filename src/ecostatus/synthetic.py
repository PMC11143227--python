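"""Synthetic ocean fixtures with known ground truth.

This module emulates, at desk scale, the inputs of the ecological-status
pipeline: a marker-gene catalog with pathway membership, mapped-read tables
with known RPKG ground truth, smooth latitudinally structured environmental
fields for a "present" and a perturbed "future" scenario, and an invertible
(at zero noise) mapping from the ten environmental factors to the 26 microbial
indices with latent status classes.

The truth mapping is the keystone: it partitions environment space into K
latent statuses by thresholding a linear climate score, and places each
status's index vector at a well-separated archetype centroid plus a smooth
environmental modulation. Recovery experiments (clustering, classification,
regression, projection, attribution) are all judged against this ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .constants import (
    DOMINANT_TAXA,
    FACTOR_RANGES,
    FACTOR_UNITS,
    FACTORS,
    INDEX_NAMES,
    PATHWAY_CYCLE,
    PATHWAYS,
    STATUS_FEATURES,
)
from .quant import MarkerQuantTable

__all__ = [
    "GridSpec",
    "TruthMapping",
    "gen_gene_catalog",
    "gen_read_table",
    "gen_env_grid",
    "gen_env_samples",
    "gen_index_fields",
    "gen_labeled_env_samples",
    "make_truth_mapping",
    "random_ocean_mask",
    "perturbation_for_changed_fraction",
]


# --------------------------------------------------------------------------
# grid specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Regular lat-lon grid, cell-center convention, degrees east/north.

    ``ocean_mask`` is True on ocean cells; ``None`` means all-ocean.
    """

    lat_step: float = 0.5
    lon_step: float = 0.5
    lat_range: tuple[float, float] = (-80.0, 80.0)
    lon_range: tuple[float, float] = (-180.0, 180.0)
    ocean_mask: np.ndarray | None = None

    @property
    def lats(self) -> np.ndarray:
        lo, hi = self.lat_range
        return np.arange(lo + self.lat_step / 2, hi, self.lat_step)

    @property
    def lons(self) -> np.ndarray:
        lo, hi = self.lon_range
        return np.arange(lo + self.lon_step / 2, hi, self.lon_step)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lats), len(self.lons))

    def __post_init__(self) -> None:
        if self.lat_step <= 0 or self.lon_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.ocean_mask is not None:
            mask = np.asarray(self.ocean_mask, dtype=bool)
            if mask.shape != self.shape:
                raise ValueError(
                    f"ocean_mask shape {mask.shape} != grid shape {self.shape}"
                )
            object.__setattr__(self, "ocean_mask", mask)

    def mask(self) -> np.ndarray:
        """Boolean ocean mask, materialized (all True when unset)."""
        if self.ocean_mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.ocean_mask


def random_ocean_mask(
    spec: GridSpec, land_fraction: float = 0.25, seed: int = 0
) -> np.ndarray:
    """Smooth pseudo-continent mask: True on ocean.

    Thresholds a Gaussian-smoothed white-noise field so that about
    ``land_fraction`` of cells become land, in contiguous blobs.
    """
    if not 0 <= land_fraction < 1:
        raise ValueError("land_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=spec.shape)
    smooth = gaussian_filter(noise, sigma=max(2, min(spec.shape) / 10), mode="wrap")
    cut = np.quantile(smooth, 1 - land_fraction)
    return smooth < cut


# --------------------------------------------------------------------------
# gene catalog and read tables
# --------------------------------------------------------------------------

def gen_gene_catalog(
    n_pathways: int = 19, genes_per_pathway: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Marker-gene catalog: ``gene_id``, ``length_kbp``, ``pathway``, ``element_cycle``.

    Gene lengths are uniform in [0.3, 3.0] kbp. Pathway names follow the
    default 19-pathway list, cycling if ``n_pathways`` exceeds it.
    """
    if n_pathways < 1 or genes_per_pathway < 1:
        raise ValueError("n_pathways and genes_per_pathway must be >= 1")
    rng = np.random.default_rng(seed)
    pathways = [PATHWAYS[i % len(PATHWAYS)] if i < len(PATHWAYS) else f"pathway_{i}"
                for i in range(n_pathways)]
    rows = []
    for p in pathways:
        cycle = PATHWAY_CYCLE.get(p, "carbon fixation")
        for g in range(genes_per_pathway):
            rows.append(
                {
                    "gene_id": f"{p}__g{g}",
                    "length_kbp": float(np.round(rng.uniform(0.3, 3.0), 4)),
                    "pathway": p,
                    "element_cycle": cycle,
                }
            )
    cat = pd.DataFrame(rows)
    assert cat["gene_id"].is_unique
    return cat


def gen_read_table(
    catalog: pd.DataFrame,
    n_samples: int,
    target_rpkg: pd.DataFrame | np.ndarray | float,
    seed: int = 0,
) -> MarkerQuantTable:
    """Read counts whose RPKG quantification returns ``target_rpkg``.

    Inverts the RPKG definition: reads = round(RPKG * length_kbp * genome
    equivalents), with library size and average genome size drawn per sample.
    ``target_rpkg`` may be a scalar, a per-gene vector, or an
    (n_samples, n_genes) array/frame.
    """
    genes = catalog["gene_id"].to_numpy()
    lengths = catalog["length_kbp"].to_numpy(dtype=float)
    target = np.asarray(
        target_rpkg.to_numpy() if isinstance(target_rpkg, pd.DataFrame) else target_rpkg,
        dtype=float,
    )
    target = np.broadcast_to(np.atleast_2d(target), (n_samples, len(genes))).copy()
    if not np.all(np.isfinite(target)):
        raise ValueError("target_rpkg must be finite")
    if np.any(target < 0):
        raise ValueError("target_rpkg must be non-negative")

    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    ags_bp = rng.uniform(2e6, 6e6, size=n_samples)
    library_size_bp = rng.integers(int(5e8), int(5e9), size=n_samples)
    genome_eq = library_size_bp / ags_bp
    reads = np.rint(target * lengths[None, :] * genome_eq[:, None]).astype(np.int64)
    return MarkerQuantTable(
        reads=pd.DataFrame(reads, index=pd.Index(sample_ids, name="sample_id"),
                           columns=pd.Index(genes, name="gene_id")),
        library_size_bp=pd.Series(library_size_bp, index=sample_ids, name="library_size_bp"),
        ags_bp=pd.Series(ags_bp, index=sample_ids, name="ags_bp"),
    )


# --------------------------------------------------------------------------
# environmental grids
# --------------------------------------------------------------------------

# Per-factor latitudinal shape: (poleward sign, exponent). sign=-1 means the
# factor decreases toward the poles (temperature-like); +1 increases.
_LAT_SHAPE: dict[str, tuple[float, float]] = {
    "temperature": (-1, 1.2),
    "salinity": (-1, 2.0),
    "pco2": (-1, 1.5),
    "mixed_layer_depth": (+1, 1.5),
    "oxygen": (+1, 1.0),
    "nitrate": (+1, 1.2),
    "phosphate": (+1, 1.0),
    "silicate": (+1, 1.4),
    "carbonate": (-1, 1.0),
    "iron": (-1, 1.8),
}


def _present_field(spec: GridSpec, factor: str, rng: np.random.Generator) -> np.ndarray:
    lo, hi = FACTOR_RANGES[factor]
    span = hi - lo
    sign, expo = _LAT_SHAPE[factor]
    lat_frac = (np.abs(spec.lats) / max(abs(spec.lat_range[0]), abs(spec.lat_range[1]))) ** expo
    base = lat_frac if sign > 0 else 1 - lat_frac
    # keep base away from the range edges so perturbations stay meaningful
    base = 0.1 + 0.8 * base
    field2d = lo + span * base[:, None] * np.ones(len(spec.lons))[None, :]
    # zonal harmonic + smooth random structure (5% of range each)
    phase = rng.uniform(0, 2 * np.pi)
    field2d += 0.05 * span * np.sin(np.deg2rad(spec.lons) + phase)[None, :]
    noise = rng.normal(size=spec.shape)
    noise = gaussian_filter(noise, sigma=max(2, min(spec.shape) / 12), mode="wrap")
    sd = noise.std()
    if sd > 0:
        field2d += 0.05 * span * noise / sd
    return field2d


def gen_env_grid(
    spec: GridSpec,
    scenario: str = "present",
    perturbation: dict[str, float | np.ndarray] | None = None,
    seed: int = 0,
) -> xr.Dataset:
    """Smooth latitudinally structured fields for all ten factors.

    For a fixed ``seed`` the underlying present-day fields are identical
    across calls; a non-empty ``perturbation`` (factor -> scalar or 2-D
    offset) is added on top, so future minus present equals the perturbation
    exactly on ocean cells. Land cells are NaN.
    """
    perturbation = perturbation or {}
    unknown = set(perturbation) - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown factor(s) in perturbation: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    mask = spec.mask()
    data = {}
    for f in FACTORS:  # fixed order keeps rng draws aligned across calls
        arr = _present_field(spec, f, rng)
        if f in perturbation:
            arr = arr + np.asarray(perturbation[f], dtype=float)
        arr = np.where(mask, arr, np.nan)
        da = xr.DataArray(arr, coords={"lat": spec.lats, "lon": spec.lons},
                          dims=("lat", "lon"), name=f)
        da.attrs["units"] = FACTOR_UNITS[f]
        data[f] = da
    ds = xr.Dataset(data)
    ds.attrs["scenario"] = scenario
    ds.attrs["lat_step"] = spec.lat_step
    ds.attrs["lon_step"] = spec.lon_step
    ds.attrs["convention"] = "cell-center"
    return ds


def gen_env_samples(n: int, seed: int = 0) -> pd.DataFrame:
    """Random environmental vectors, uniform within each factor's range."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {f: rng.uniform(*FACTOR_RANGES[f], size=n) for f in FACTORS}
    return pd.DataFrame(cols, index=pd.Index([f"E{i:05d}" for i in range(n)]))


def env_to_frame(env: xr.Dataset) -> pd.DataFrame:
    """Ocean cells of an environmental grid as a (cell, factor) frame.

    Index is a (lat, lon) MultiIndex over cells where all factors are finite.
    """
    missing = [f for f in FACTORS if f not in env.data_vars]
    if missing:
        raise ValueError(f"environment grid is missing factor(s): {missing}")
    df = env[list(FACTORS)].to_dataframe()[list(FACTORS)]
    return df.dropna()


# --------------------------------------------------------------------------
# truth mapping: environment -> indices + latent status
# --------------------------------------------------------------------------

@dataclass
class TruthMapping:
    """Ground-truth environment-to-microbiome relation with latent statuses.

    The climate score ``s = w . z(env)`` (z-scored by fixed reference
    statistics) is cut at ``thresholds`` into K latent classes; each class has
    a 25-feature archetype centroid, modulated smoothly by the environment
    through ``env_loadings`` and perturbed by isotropic noise of sd
    ``noise_sd``. Richness is generated independent of the environment
    (constant at zero noise), mirroring its real-world unpredictability.
    """

    archetypes: np.ndarray          # (K, 25) in STATUS_FEATURES order
    env_loadings: np.ndarray        # (25, 10)
    env_scale: float
    status_weights: np.ndarray      # (10,) in FACTORS order
    thresholds: np.ndarray          # (K-1,) ascending score cuts
    ref_mean: np.ndarray            # (10,)
    ref_sd: np.ndarray              # (10,)
    noise_sd: float = 0.0
    richness_base: float = 500.0
    richness_noise_scale: float = 50.0
    seed: int = 0

    @property
    def n_status(self) -> int:
        return self.archetypes.shape[0]

    def _z(self, env_values: np.ndarray) -> np.ndarray:
        return (env_values - self.ref_mean) / self.ref_sd

    def score(self, env_values: np.ndarray) -> np.ndarray:
        return self._z(np.asarray(env_values, dtype=float)) @ self.status_weights

    def status(self, env: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Latent status labels 1..K (deterministic partition of env space)."""
        values = env[list(FACTORS)].to_numpy() if isinstance(env, pd.DataFrame) else env
        return np.searchsorted(self.thresholds, self.score(values), side="right") + 1

    def indices(self, env: pd.DataFrame, rng: np.random.Generator | None = None) -> pd.DataFrame:
        """The 26 microbial indices for each environmental vector."""
        values = env[list(FACTORS)].to_numpy(dtype=float)
        labels = self.status(values)
        z = self._z(values)
        feats = self.archetypes[labels - 1] + self.env_scale * np.tanh(z @ self.env_loadings.T)
        richness = np.full(len(values), self.richness_base)
        if self.noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng(self.seed)
            feats = feats + rng.normal(0, self.noise_sd, size=feats.shape)
            richness = richness + rng.normal(
                0, self.noise_sd * self.richness_noise_scale, size=len(values)
            )
        out = pd.DataFrame(feats, index=env.index, columns=list(STATUS_FEATURES))
        out.insert(len(DOMINANT_TAXA), "richness", richness)
        return out[list(INDEX_NAMES)]


def make_truth_mapping(
    env: xr.Dataset | pd.DataFrame,
    n_status: int = 7,
    seed: int = 0,
    noise_sd: float = 0.0,
    separation: float = 8.0,
    within_sd: float = 0.5,
    status_weights: dict[str, float] | None = None,
) -> TruthMapping:
    """Build a truth mapping calibrated on an environmental sample.

    Thresholds are equal-frequency quantiles of the climate score over the
    supplied environment (grid ocean cells or sample table), giving ~balanced
    latent classes. Archetype centroids are scaled so the minimum pairwise
    distance is ``separation`` times the total within-class standard
    deviation (``within_sd`` per feature, isotropic bound).
    """
    if n_status < 2:
        raise ValueError("n_status must be >= 2")
    frame = env_to_frame(env) if isinstance(env, xr.Dataset) else env
    ranges = np.array([FACTOR_RANGES[f] for f in FACTORS])
    ref_mean = ranges.mean(axis=1)
    ref_sd = (ranges[:, 1] - ranges[:, 0]) / 4.0

    if status_weights is None:
        # phosphate thresholds by default: axis-aligned rule, mirroring
        # phosphate's top importance for real-ocean status classification
        status_weights = {"phosphate": 1.0}
    unknown = set(status_weights) - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown factor(s) in status_weights: {sorted(unknown)}")
    w = np.array([status_weights.get(f, 0.0) for f in FACTORS])
    if not np.any(w != 0):
        raise ValueError("status_weights must have at least one non-zero entry")

    z = (frame[list(FACTORS)].to_numpy(dtype=float) - ref_mean) / ref_sd
    score = z @ w
    qs = np.arange(1, n_status) / n_status
    thresholds = np.quantile(score, qs)

    rng = np.random.default_rng(seed)
    d = len(STATUS_FEATURES)
    centroids = rng.normal(size=(n_status, d))
    dists = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    d_min = dists[np.triu_indices(n_status, k=1)].min()
    target = separation * within_sd * np.sqrt(d)
    archetypes = 10.0 + centroids * (target / d_min)

    loadings = rng.normal(size=(d, len(FACTORS))) / np.sqrt(len(FACTORS))
    return TruthMapping(
        archetypes=archetypes,
        env_loadings=loadings,
        env_scale=within_sd,
        status_weights=w,
        thresholds=thresholds,
        ref_mean=ref_mean,
        ref_sd=ref_sd,
        noise_sd=noise_sd,
        seed=seed,
    )


def gen_labeled_env_samples(
    truth: TruthMapping,
    n: int,
    seed: int = 0,
    margin: float = 0.0,
    label_noise: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Random environmental vectors with their latent status labels.

    ``margin`` > 0 rejection-samples vectors whose climate score lies within
    ``margin`` times the narrowest inter-threshold band of a status boundary,
    i.e. the latent classes are separated by empty buffer zones - the
    "well-separated archetypes" regime. ``label_noise`` flips each label to a
    uniformly random other class with that probability (applied after the
    margin filter).
    """
    if not 0 <= label_noise < 1:
        raise ValueError("label_noise must be in [0, 1)")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    rng = np.random.default_rng(seed)
    collected: list[pd.DataFrame] = []
    total = 0
    attempt = 0
    while total < n:
        attempt += 1
        if attempt > 50:
            raise RuntimeError("margin too wide: rejection sampling stalled")
        batch = gen_env_samples(max(n, 1000), seed=int(rng.integers(2**31)))
        if margin > 0:
            s = truth.score(batch[list(FACTORS)].to_numpy())
            edges = np.concatenate([[s.min()], truth.thresholds, [s.max()]])
            band = np.min(np.diff(edges))
            dist = np.min(np.abs(s[:, None] - truth.thresholds[None, :]), axis=1)
            batch = batch[dist >= margin * band]
        collected.append(batch)
        total += len(batch)
    env = pd.concat(collected).iloc[:n]
    env.index = pd.Index([f"E{i:06d}" for i in range(n)])
    labels = pd.Series(truth.status(env), index=env.index, name="status")
    if label_noise > 0:
        flip = rng.random(n) < label_noise
        k = truth.n_status
        shifted = (labels[flip] - 1 + rng.integers(1, k, flip.sum())) % k + 1
        labels[flip] = shifted
    return env, labels


def gen_index_fields(
    env: xr.Dataset, truth: TruthMapping
) -> tuple[xr.Dataset, xr.DataArray]:
    """Index grid (26 variables) plus the latent status label field.

    Land (NaN) cells stay NaN in every output field. At ``noise_sd = 0`` the
    output is a pure function of the environment.
    """
    frame = env_to_frame(env)
    rng = np.random.default_rng(truth.seed) if truth.noise_sd > 0 else None
    idx = truth.indices(frame, rng=rng)
    labels = truth.status(frame)

    template = env[FACTORS[0]]
    coords = {"lat": template["lat"].values, "lon": template["lon"].values}
    out = {}
    for name in INDEX_NAMES:
        vals = pd.Series(idx[name].to_numpy(), index=frame.index)
        out[name] = xr.DataArray(_scatter(template, vals), coords=coords,
                                 dims=("lat", "lon"), name=name)
    status = xr.DataArray(
        _scatter(template, pd.Series(labels.astype(float), index=frame.index)),
        coords=coords, dims=("lat", "lon"), name="status",
    )
    grid = xr.Dataset(out)
    grid.attrs.update(env.attrs)
    return grid, status


def _scatter(template: xr.DataArray, values: pd.Series) -> np.ndarray:
    """Place (lat, lon)-indexed values into a 2-D array shaped like template."""
    lat_index = pd.Index(template["lat"].values)
    lon_index = pd.Index(template["lon"].values)
    arr = np.full(template.shape, np.nan)
    lats = values.index.get_level_values("lat")
    lons = values.index.get_level_values("lon")
    arr[lat_index.get_indexer(lats), lon_index.get_indexer(lons)] = values.to_numpy()
    return arr


def perturbation_for_changed_fraction(
    env: xr.Dataset,
    truth: TruthMapping,
    factor: str = "phosphate",
    fraction: float = 0.25,
) -> tuple[dict[str, float], xr.DataArray]:
    """Uniform single-factor offset that moves ``fraction`` of ocean cells
    across their nearest lower latent-status boundary.

    Returns the perturbation dict (a negative offset on ``factor``) and the
    analytic changed-cell mask implied by the truth rule. Requires the factor
    to carry positive weight in the status rule.
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor: {factor}")
    i = FACTORS.index(factor)
    w_f = truth.status_weights[i] / truth.ref_sd[i]
    if w_f <= 0:
        raise ValueError(f"{factor} must have positive weight in the status rule")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")

    frame = env_to_frame(env)
    s = truth.score(frame[list(FACTORS)].to_numpy())
    pos = np.searchsorted(truth.thresholds, s, side="right")  # class index - 1
    dist = np.full(len(s), np.inf)
    above = pos > 0
    dist[above] = (s[above] - truth.thresholds[pos[above] - 1]) / w_f
    finite_frac = np.mean(np.isfinite(dist))
    if fraction >= finite_frac:
        raise ValueError("requested fraction exceeds the movable share of cells")
    delta = float(np.quantile(np.where(np.isfinite(dist), dist, np.inf), fraction,
                              method="higher"))
    changed_cells = dist <= delta
    if abs(changed_cells.mean() - fraction) > 0.02:
        warnings.warn("achieved changed fraction deviates from request by > 2pp")

    # nudge the offset so cells sitting exactly on the quantile do cross
    offset = -(delta * (1 + 1e-9) + 1e-12)
    template = env[FACTORS[0]]
    mask = xr.DataArray(
        _scatter(template, pd.Series(changed_cells.astype(float), index=frame.index)),
        coords={"lat": template["lat"].values, "lon": template["lon"].values},
        dims=("lat", "lon"), name="changed_truth",
    )
    return {factor: offset}, mask
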