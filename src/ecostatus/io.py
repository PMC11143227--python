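"""Readers/writers, pipeline configuration and the end-to-end orchestrator.

Grids travel as NetCDF (named lat/lon dimensions, units attributes, written
through xarray's scipy backend), tables as TSV with a one-line header,
summaries as JSON. `run_pipeline` wires the stages in the order the analysis
runs - simulate, quantify, cluster, train, project, attribute - and stamps
every run with a config hash, the seeds, and the package version in a
provenance manifest. A rerun with the same config reproduces the
deterministic outputs; resuming into an output directory whose manifest
carries a different config hash is refused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .attribution import dominant_driver, relative_contributions
from .cluster import assign_status, build_feature_matrix, tune_hierarchical
from .constants import FACTORS, PATHWAYS
from .models import (balanced_sample, fit_index_regressors, tune_classifier)
from .projection import (changed_fraction, index_change_summary,
                         project_scenario, status_composition)
from .quant import aggregate_pathways, quantify, shannon_richness
from .synthetic import (GridSpec, gen_env_grid, gen_gene_catalog,
                        gen_index_fields, gen_read_table, make_truth_mapping,
                        perturbation_for_changed_fraction, random_ocean_mask)

__all__ = ["PipelineConfig", "read_grid", "write_grid", "read_table",
           "write_table", "run_pipeline"]

log = logging.getLogger("ecostatus")


# --------------------------------------------------------------------------
# grid and table I/O
# --------------------------------------------------------------------------

def write_grid(grid: xr.Dataset | xr.DataArray, path) -> None:
    """Write a gridded field set as NetCDF (lat/lon dims, attrs preserved)."""
    ds = grid.to_dataset() if isinstance(grid, xr.DataArray) else grid
    ds.to_netcdf(path, engine="scipy")


def read_grid(path, expect_factors: bool = False) -> xr.Dataset:
    """Read a NetCDF grid; optionally insist on the ten factor variables."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ds = xr.load_dataset(path, engine="scipy")
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ValueError(f"cannot parse grid file {path}: {exc}") from exc
    for dim in ("lat", "lon"):
        if dim not in ds.dims:
            raise ValueError(f"grid file {path} lacks dimension {dim!r}")
    if expect_factors:
        missing = [f for f in FACTORS if f not in ds.data_vars]
        if missing:
            raise ValueError(f"grid file {path} missing factor variable(s): {missing}")
    return ds


def check_grid_compat(a: xr.Dataset, b: xr.Dataset) -> None:
    """Refuse to combine grids with different steps or coordinates."""
    for dim in ("lat", "lon"):
        av, bv = a[dim].values, b[dim].values
        if len(av) != len(bv) or not np.allclose(av, bv):
            raise ValueError(f"grid step/coordinate mismatch on {dim!r}")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_table(path, index_col: int = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", index_col=index_col)
    except Exception as exc:
        raise ValueError(f"cannot parse table {path}: {exc}") from exc


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Explicit-everything configuration of a pipeline run.

    Unknown keys are rejected on load; the canonical JSON serialization
    round-trips unchanged and its SHA-256 is the run's identity.
    """

    seed: int = 0
    lat_step: float = 4.0
    lon_step: float = 4.0
    lat_range: tuple[float, float] = (-80.0, 80.0)
    lon_range: tuple[float, float] = (-180.0, 180.0)
    land_fraction: float = 0.25
    n_status: int = 7
    noise_sd: float = 0.0
    separation: float = 8.0
    perturb_factor: str = "phosphate"
    perturb_fraction: float = 0.25
    pathways: tuple[str, ...] = PATHWAYS
    genes_per_pathway: int = 3
    n_samples: int = 24
    k_range: tuple[int, ...] = tuple(range(2, 13))
    n_per_class: int = 60
    classifier_families: tuple[str, ...] = ("xgboost", "logistic")
    regressor_families: tuple[str, ...] = ("random_forest", "linear")
    regressor_indices: tuple[str, ...] = ("Cyanobacteria", "shannon", "calvin_cycle")
    weighting: str = "cell_count"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run simulate -> quantify -> cluster -> train -> project -> attribute.

    Writes every stage artifact under ``out_dir`` and returns the provenance
    manifest (also written as ``manifest.json``). Stage failures abort with
    the failing stage named.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") != config.hash():
            raise RuntimeError(
                "output directory holds artifacts from a different config "
                "(hash mismatch); refusing to mix runs"
            )

    manifest: dict = {
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    stage = "simulate"
    try:
        log.info("stage %s", stage)
        spec = GridSpec(config.lat_step, config.lon_step,
                        tuple(config.lat_range), tuple(config.lon_range))
        spec = GridSpec(config.lat_step, config.lon_step,
                        tuple(config.lat_range), tuple(config.lon_range),
                        ocean_mask=random_ocean_mask(
                            spec, config.land_fraction, seed=config.seed))
        env_p = gen_env_grid(spec, "present", seed=config.seed)
        truth = make_truth_mapping(env_p, n_status=config.n_status,
                                   seed=config.seed, noise_sd=config.noise_sd,
                                   separation=config.separation)
        perturbation, changed_truth = perturbation_for_changed_fraction(
            env_p, truth, factor=config.perturb_factor,
            fraction=config.perturb_fraction)
        env_f = gen_env_grid(spec, "future", perturbation=perturbation,
                             seed=config.seed)
        catalog = gen_gene_catalog(len(config.pathways),
                                   config.genes_per_pathway, seed=config.seed)
        rng = np.random.default_rng(config.seed)
        targets = rng.uniform(0.0, 5.0, size=(config.n_samples, len(catalog)))
        reads = gen_read_table(catalog, config.n_samples, targets,
                               seed=config.seed)
        write_grid(env_p, out / "env_present.nc")
        write_grid(env_f, out / "env_future.nc")
        write_table(catalog, out / "catalog.tsv")
        write_table(reads.to_frame(), out / "reads.tsv")
        manifest["stages"][stage] = {
            "perturbation": perturbation,
            "files": ["env_present.nc", "env_future.nc", "catalog.tsv",
                      "reads.tsv"],
        }

        stage = "quantify"
        log.info("stage %s", stage)
        gene_rpkg = quantify(reads, catalog)
        pathway_rpkg = aggregate_pathways(gene_rpkg, catalog)
        diversity = shannon_richness(gene_rpkg)
        write_table(gene_rpkg, out / "gene_rpkg.tsv")
        write_table(pathway_rpkg, out / "pathway_rpkg.tsv")
        write_table(diversity, out / "diversity.tsv")
        manifest["stages"][stage] = {
            "n_samples": int(len(gene_rpkg)),
            "files": ["gene_rpkg.tsv", "pathway_rpkg.tsv", "diversity.tsv"],
        }

        stage = "cluster"
        log.info("stage %s", stage)
        index_grid, latent = gen_index_fields(env_p, truth)
        write_grid(index_grid, out / "indices_present.nc")
        fm = build_feature_matrix(index_grid)
        tuning = tune_hierarchical(fm, k_range=config.k_range)
        labeling = assign_status(fm, tuning.best_k, tuning.best_linkage,
                                 tuning.best_metric)
        status_grid = labeling.to_grid(env_p[FACTORS[0]])
        write_grid(status_grid, out / "status_present.nc")
        write_table(tuning.records, out / "cluster_tuning.tsv")
        log.info("clustering chose k=%d %s/%s (silhouette %.3f)",
                 tuning.best_k, tuning.best_linkage, tuning.best_metric,
                 tuning.best_silhouette)
        manifest["stages"][stage] = {
            "k": tuning.best_k, "linkage": tuning.best_linkage,
            "metric": tuning.best_metric,
            "silhouette": tuning.best_silhouette,
            "files": ["indices_present.nc", "status_present.nc",
                      "cluster_tuning.tsv"],
        }

        stage = "train"
        log.info("stage %s", stage)
        env_frame = env_p[list(FACTORS)].to_dataframe()[list(FACTORS)].dropna()
        labels = labeling.labels
        train_ids, test_ids = balanced_sample(labels, config.n_per_class,
                                              seed=config.seed)
        clf = tune_classifier(env_frame.loc[train_ids], labels.loc[train_ids],
                              env_frame.loc[test_ids], labels.loc[test_ids],
                              families=config.classifier_families,
                              seed=config.seed)
        idx_frame = index_grid.to_dataframe().dropna()
        reg = fit_index_regressors(
            env_frame.loc[idx_frame.index],
            idx_frame[list(config.regressor_indices)],
            families=config.regressor_families, seed=config.seed)
        write_table(reg.scores(), out / "regressor_scores.tsv")
        if clf.confusion is not None:
            write_table(clf.confusion, out / "confusion.tsv")
        manifest["stages"][stage] = {
            "classifier_family": clf.family,
            "classifier_params": {k: v for k, v in clf.params.items()},
            "cv_accuracy": clf.cv_accuracy,
            "train_accuracy": clf.train_accuracy,
            "test_accuracy": clf.test_accuracy,
            "regressor_test_r2": {k: reg.results[k].r2_test
                                  for k in reg.retained},
            "files": ["regressor_scores.tsv", "confusion.tsv"],
        }

        stage = "project"
        log.info("stage %s", stage)
        cm = project_scenario(clf, env_p, env_f)
        frac = changed_fraction(cm, weighting=config.weighting)
        summary = status_composition(cm, weighting=config.weighting)
        changes = index_change_summary(reg, env_p, env_f,
                                       changed_mask=cm.changed)
        write_grid(cm.status_future, out / "status_future.nc")
        write_grid(cm.changed.rename("changed"), out / "changed.nc")
        write_table(summary.transition, out / "transition.tsv")
        write_table(changes["band_means"], out / "index_band_means.tsv")
        manifest["stages"][stage] = {
            "changed_fraction_pct": frac,
            "target_changed_fraction_pct": 100.0 * config.perturb_fraction,
            "composition_present": summary.composition_present.to_dict(),
            "composition_future": summary.composition_future.to_dict(),
            "pct_increase": changes["pct_increase"].to_dict(),
            "files": ["status_future.nc", "changed.nc", "transition.tsv",
                      "index_band_means.tsv"],
        }

        stage = "attribute"
        log.info("stage %s", stage)
        attr = relative_contributions(clf, env_p, env_f, scope=cm.changed)
        dom = dominant_driver(attr)
        write_grid(attr.rc, out / "attribution_rc.nc")
        if dom["dominant"].notnull().any():
            write_grid(dom["dominant"], out / "dominant_driver.nc")
        manifest["stages"][stage] = {
            "factor_share_pct": dom["factor_share"].to_dict(),
            "group_share_pct": dom["group_share"].to_dict(),
            "files": ["attribution_rc.nc", "dominant_driver.nc"],
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # per-artifact hashes -> deterministic manifest hash for the run
    hashes = {}
    for info in manifest["stages"].values():
        for f in info.get("files", []):
            p = out / f
            if p.exists():
                hashes[f] = _sha256(p)
    manifest["artifact_hashes"] = hashes
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(hashes, sort_keys=True).encode()).hexdigest()
    manifest_path.write_text(json.dumps(manifest, indent=1, default=float))
    return manifest
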