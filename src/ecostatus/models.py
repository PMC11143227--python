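"""Environment-driven supervised models.

Per-index regressions map the ten environmental factors to each microbial
index (tenfold-CV tuning over several algorithm families on an 80/20 split;
indices whose best held-out R^2 stays below a threshold are excluded, the way
richness is excluded in practice). The status classifier is trained on a
balanced per-class sample of labeled cells, tuned by tenfold CV, and exposes
calibrated per-status probabilities for scenario projection and attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
import xarray as xr
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix, r2_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier, XGBRegressor

from .constants import FACTORS

__all__ = [
    "RegressorResult",
    "RegressionBundle",
    "ClassifierBundle",
    "tune_regressor",
    "fit_index_regressors",
    "predict_indices",
    "balanced_sample",
    "tune_classifier",
    "predict_status_proba",
    "save_bundle",
    "load_bundle",
]

BUNDLE_SCHEMA_VERSION = 1

# (estimator factory, hyperparameter grid). Grids are deliberately small;
# published tuning grids for this kind of study are rarely complete, so these
# cover the printed best points plus cheap alternatives.
def regressor_families(seed: int) -> dict[str, tuple[object, dict]]:
    return {
        "random_forest": (
            RandomForestRegressor(random_state=seed, n_jobs=1),
            {"n_estimators": [100], "min_samples_leaf": [1, 5]},
        ),
        "gradient_boosting": (
            XGBRegressor(random_state=seed, n_jobs=1, tree_method="hist",
                         verbosity=0),
            {"n_estimators": [200], "max_depth": [3, 6], "learning_rate": [0.1]},
        ),
        "linear": (LinearRegression(), {}),
        "lasso": (Lasso(max_iter=5000), {"alpha": [0.001, 0.01, 0.1]}),
        "knn": (KNeighborsRegressor(), {"n_neighbors": [5, 15]}),
    }


def classifier_families(seed: int) -> dict[str, tuple[object, dict]]:
    return {
        "xgboost": (
            # exact greedy splits: histogram binning cannot place thresholds
            # inside narrow inter-class gaps, which costs boundary accuracy
            XGBClassifier(random_state=seed, n_jobs=1, tree_method="exact",
                          verbosity=0, eval_metric="mlogloss"),
            # includes the printed best point: 200 trees, depth 9, lr 0.3
            {"n_estimators": [200], "max_depth": [3, 9], "learning_rate": [0.3]},
        ),
        "random_forest": (
            RandomForestClassifier(random_state=seed, n_jobs=1),
            {"n_estimators": [200]},
        ),
        "logistic": (
            Pipeline([("scale", StandardScaler()),
                      ("clf", LogisticRegression(max_iter=2000))]),
            {"clf__C": [1.0]},
        ),
        "svm": (
            Pipeline([("scale", StandardScaler()),
                      ("clf", SVC(probability=True, random_state=seed))]),
            {"clf__C": [1.0]},
        ),
    }


def _feature_importance(model, X: np.ndarray, y: np.ndarray,
                        seed: int) -> np.ndarray:
    """Per-factor importance, normalized to sum to 1."""
    est = model.named_steps["clf"] if isinstance(model, Pipeline) else model
    if hasattr(est, "feature_importances_"):
        imp = np.asarray(est.feature_importances_, dtype=float)
    elif hasattr(est, "coef_"):
        coef = np.atleast_2d(est.coef_)
        imp = np.abs(coef).mean(axis=0) * X.std(axis=0)
    else:
        r = permutation_importance(model, X, y, n_repeats=5, random_state=seed)
        imp = np.clip(r.importances_mean, 0, None)
    total = imp.sum()
    return imp / total if total > 0 else np.full(len(imp), 1 / len(imp))


# --------------------------------------------------------------------------
# regression
# --------------------------------------------------------------------------

@dataclass
class RegressorResult:
    index: str
    family: str | None
    params: dict | None
    model: object | None
    cv_r2: float
    r2_train: float
    r2_test: float
    importance: pd.Series | None
    excluded: bool = False
    reason: str | None = None


def tune_regressor(X: pd.DataFrame, y: pd.Series | np.ndarray,
                   families=None, grids: dict[str, dict] | None = None,
                   seed: int = 0, test_size: float = 0.2,
                   cv: int = 10, exclude_threshold: float = 0.1,
                   name: str = "index") -> RegressorResult:
    """Tune one per-index regression across algorithm families.

    80/20 split; tenfold CV (R^2) over each family's grid on the training
    portion; the best family is refit and scored on the held-out test set.
    A best test R^2 below ``exclude_threshold`` (or a constant target)
    excludes the index with a recorded reason.
    """
    Xv = X[list(FACTORS)].to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(Xv) < 50:
        raise ValueError("need at least 50 samples to tune a regressor")
    if np.std(yv) == 0:
        return RegressorResult(index=name, family=None, params=None, model=None,
                               cv_r2=np.nan, r2_train=np.nan, r2_test=np.nan,
                               importance=None, excluded=True,
                               reason="constant target")
    all_families = regressor_families(seed)
    chosen = {f: all_families[f] for f in (families or all_families)}
    if not chosen:
        raise ValueError("families must be non-empty")

    X_tr, X_te, y_tr, y_te = train_test_split(Xv, yv, test_size=test_size,
                                              random_state=seed)
    folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
    best = None
    for fam, (est, grid) in chosen.items():
        if grids and fam in grids:
            grid = grids[fam]
        search = GridSearchCV(clone(est), grid, cv=folds, scoring="r2", n_jobs=1)
        search.fit(X_tr, y_tr)
        if best is None or search.best_score_ > best[2]:
            best = (fam, search.best_estimator_, search.best_score_,
                    search.best_params_)
    fam, model, cv_r2, params = best
    r2_tr = r2_score(y_tr, model.predict(X_tr))
    r2_te = r2_score(y_te, model.predict(X_te))
    imp = pd.Series(_feature_importance(model, X_tr, y_tr, seed),
                    index=list(FACTORS), name=name)
    excluded = r2_te < exclude_threshold
    return RegressorResult(
        index=name, family=fam, params=params, model=model, cv_r2=float(cv_r2),
        r2_train=float(r2_tr), r2_test=float(r2_te), importance=imp,
        excluded=excluded,
        reason=f"test R^2 {r2_te:.3f} < {exclude_threshold}" if excluded else None,
    )


@dataclass
class RegressionBundle:
    """One tuned regressor per retained index, plus the exclusion record."""

    results: dict[str, RegressorResult]
    seed: int = 0

    @property
    def retained(self) -> list[str]:
        return [k for k, r in self.results.items() if not r.excluded]

    @property
    def excluded(self) -> dict[str, str]:
        return {k: r.reason for k, r in self.results.items() if r.excluded}

    def scores(self) -> pd.DataFrame:
        rows = [{"index": k, "family": r.family, "cv_r2": r.cv_r2,
                 "r2_train": r.r2_train, "r2_test": r.r2_test,
                 "excluded": r.excluded, "reason": r.reason}
                for k, r in self.results.items()]
        return pd.DataFrame(rows).set_index("index")


def fit_index_regressors(env: pd.DataFrame, indices: pd.DataFrame,
                         families=None, seed: int = 0,
                         exclude_threshold: float = 0.1) -> RegressionBundle:
    """Tune one regression per index column (factor table -> index table)."""
    results = {}
    for col in indices.columns:
        results[col] = tune_regressor(env, indices[col], families=families,
                                      seed=seed, name=col,
                                      exclude_threshold=exclude_threshold)
    return RegressionBundle(results=results, seed=seed)


def predict_indices(bundle: RegressionBundle,
                    env: xr.Dataset | pd.DataFrame) -> xr.Dataset | pd.DataFrame:
    """Predicted fields for every retained index; masked cells stay masked."""
    if isinstance(env, pd.DataFrame):
        missing = [f for f in FACTORS if f not in env.columns]
        if missing:
            raise ValueError(f"missing factor(s): {missing}")
        X = env[list(FACTORS)].to_numpy(dtype=float)
        return pd.DataFrame(
            {k: bundle.results[k].model.predict(X) for k in bundle.retained},
            index=env.index,
        )
    missing = [f for f in FACTORS if f not in env.data_vars]
    if missing:
        raise ValueError(f"missing factor(s): {missing}")
    frame = env[list(FACTORS)].to_dataframe()[list(FACTORS)].dropna()
    preds = pd.DataFrame(
        {k: bundle.results[k].model.predict(frame.to_numpy()) for k in bundle.retained},
        index=frame.index,
    )
    template = env[FACTORS[0]]
    out = {}
    lat_index = pd.Index(template["lat"].values)
    lon_index = pd.Index(template["lon"].values)
    ii = lat_index.get_indexer(frame.index.get_level_values("lat"))
    jj = lon_index.get_indexer(frame.index.get_level_values("lon"))
    for k in bundle.retained:
        arr = np.full(template.shape, np.nan)
        arr[ii, jj] = preds[k].to_numpy()
        out[k] = xr.DataArray(arr, coords={"lat": lat_index.values,
                                           "lon": lon_index.values},
                              dims=("lat", "lon"), name=k)
    return xr.Dataset(out)


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def balanced_sample(labels: pd.Series, n_per_class: int, seed: int = 0,
                    oversample: bool = False) -> tuple[pd.Index, pd.Index]:
    """Exactly ``n_per_class`` training ids per status; the rest is the test
    set. Without-replacement by default; classes smaller than ``n_per_class``
    raise unless ``oversample`` allows with-replacement sampling."""
    rng = np.random.default_rng(seed)
    values = labels.to_numpy()
    train_pos = []
    for g in np.unique(values):
        pos = np.flatnonzero(values == g)
        if len(pos) < n_per_class and not oversample:
            raise ValueError(
                f"class {g} has {len(pos)} members < n_per_class={n_per_class}"
            )
        take = rng.choice(pos, size=n_per_class, replace=len(pos) < n_per_class)
        train_pos.append(take)
    train_pos = np.concatenate(train_pos)
    test_pos = np.setdiff1d(np.arange(len(labels)), train_pos)
    return labels.index[train_pos], labels.index[test_pos]


@dataclass
class ClassifierBundle:
    """Fitted probabilistic status classifier plus its evaluation record."""

    model: object
    family: str
    params: dict
    classes: np.ndarray
    cv_accuracy: float
    train_accuracy: float
    test_accuracy: float | None
    confusion: pd.DataFrame | None
    importance: pd.Series
    seed: int
    schema_version: int = BUNDLE_SCHEMA_VERSION


def tune_classifier(X: pd.DataFrame, y: pd.Series | np.ndarray,
                    X_test: pd.DataFrame | None = None,
                    y_test: pd.Series | np.ndarray | None = None,
                    families=None, grids: dict[str, dict] | None = None,
                    seed: int = 0, cv: int = 10) -> ClassifierBundle:
    """Tune the status classifier by tenfold CV on the (balanced) training
    set, refit the best configuration, and evaluate on the held-out test set
    (confusion matrix included)."""
    Xv = X[list(FACTORS)].to_numpy(dtype=float)
    classes, y_enc = np.unique(np.asarray(y), return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    all_families = classifier_families(seed)
    chosen = {f: all_families[f] for f in (families or all_families)}

    folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    best = None
    for fam, (est, grid) in chosen.items():
        if grids and fam in grids:
            grid = grids[fam]
        search = GridSearchCV(clone(est), grid, cv=folds, scoring="accuracy",
                              n_jobs=1)
        search.fit(Xv, y_enc)
        if best is None or search.best_score_ > best[2]:
            best = (fam, search.best_estimator_, search.best_score_,
                    search.best_params_)
    fam, model, cv_acc, params = best
    train_acc = accuracy_score(y_enc, model.predict(Xv))

    test_acc, conf = None, None
    if X_test is not None and y_test is not None:
        Xt = X_test[list(FACTORS)].to_numpy(dtype=float)
        yt = np.searchsorted(classes, np.asarray(y_test))
        pred = model.predict(Xt)
        test_acc = float(accuracy_score(yt, pred))
        conf = pd.DataFrame(
            confusion_matrix(yt, pred, labels=np.arange(len(classes))),
            index=pd.Index(classes, name="true"),
            columns=pd.Index(classes, name="predicted"),
        )
    imp = pd.Series(_feature_importance(model, Xv, y_enc, seed),
                    index=list(FACTORS), name="importance")
    return ClassifierBundle(
        model=model, family=fam, params=params, classes=classes,
        cv_accuracy=float(cv_acc), train_accuracy=float(train_acc),
        test_accuracy=test_acc, confusion=conf, importance=imp, seed=seed,
    )


def predict_status_proba(bundle: ClassifierBundle,
                         env: xr.Dataset | pd.DataFrame
                         ) -> tuple[object, object]:
    """Per-status probabilities (summing to 1) and argmax hard labels.

    Frame input -> (probability frame with status columns, label series).
    Grid input -> (probability Dataset ``p_<status>``, status DataArray);
    masked cells stay masked.
    """
    if bundle.model is None:
        raise RuntimeError("classifier bundle is not fitted")
    if isinstance(env, pd.DataFrame):
        X = env[list(FACTORS)].to_numpy(dtype=float)
        proba = bundle.model.predict_proba(X)
        probs = pd.DataFrame(proba, index=env.index, columns=list(bundle.classes))
        labels = pd.Series(bundle.classes[proba.argmax(axis=1)], index=env.index,
                           name="status")
        return probs, labels
    missing = [f for f in FACTORS if f not in env.data_vars]
    if missing:
        raise ValueError(f"missing factor(s): {missing}")
    frame = env[list(FACTORS)].to_dataframe()[list(FACTORS)].dropna()
    proba = bundle.model.predict_proba(frame.to_numpy())
    template = env[FACTORS[0]]
    lat_index = pd.Index(template["lat"].values)
    lon_index = pd.Index(template["lon"].values)
    ii = lat_index.get_indexer(frame.index.get_level_values("lat"))
    jj = lon_index.get_indexer(frame.index.get_level_values("lon"))
    out = {}
    for c, cls in enumerate(bundle.classes):
        arr = np.full(template.shape, np.nan)
        arr[ii, jj] = proba[:, c]
        out[f"p_{cls}"] = xr.DataArray(arr, coords={"lat": lat_index.values,
                                                    "lon": lon_index.values},
                                       dims=("lat", "lon"))
    arr = np.full(template.shape, np.nan)
    arr[ii, jj] = bundle.classes[proba.argmax(axis=1)].astype(float)
    status = xr.DataArray(arr, coords={"lat": lat_index.values,
                                       "lon": lon_index.values},
                          dims=("lat", "lon"), name="status")
    return xr.Dataset(out), status


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def save_bundle(bundle, path) -> None:
    """Versioned archive of a fitted bundle (hyperparameters, seed, model)."""
    joblib.dump({"schema_version": BUNDLE_SCHEMA_VERSION, "payload": bundle}, path)


def load_bundle(path):
    blob = joblib.load(path)
    if not isinstance(blob, dict) or blob.get("schema_version") != BUNDLE_SCHEMA_VERSION:
        raise ValueError(
            f"bundle schema mismatch: expected {BUNDLE_SCHEMA_VERSION}, "
            f"got {blob.get('schema_version') if isinstance(blob, dict) else 'unknown'}"
        )
    return blob["payload"]
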