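"""Distance-based and dimension-reduction statistics.

Bray-Curtis dissimilarities between abundance profiles, PERMANOVA (adonis)
on a distance matrix, PCA with a cumulative-variance retention rule, and
rank-based group comparisons (Kruskal-Wallis omnibus + Dunn's pairwise z with
Bonferroni adjustment and Cohen's d effect sizes).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "bray_curtis",
    "permanova",
    "PermanovaResult",
    "pca_reduce",
    "PCAResult",
    "compare_groups",
]


def bray_curtis(profiles: pd.DataFrame | np.ndarray,
                ids: list[str] | None = None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix between abundance profiles.

    d(i,j) = sum|x_i - x_j| / sum(x_i + x_j), in [0, 1]. A pair of all-zero
    profiles has an undefined ratio; it is defined as 0 with a warning.
    """
    if isinstance(profiles, pd.DataFrame):
        ids = ids or [str(i) for i in profiles.index]
        x = profiles.to_numpy(dtype=float)
    else:
        x = np.asarray(profiles, dtype=float)
        ids = ids or [str(i) for i in range(len(x))]
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("need a 2-D array with at least 2 samples")
    if np.any(x < 0):
        raise ValueError("negative abundances are not allowed")
    num = pdist(x, metric="cityblock")
    totals = x.sum(axis=1)
    n = len(x)
    iu = np.triu_indices(n, k=1)
    den = totals[iu[0]] + totals[iu[1]]
    d = np.zeros_like(num)
    zero = den == 0
    if zero.any():
        warnings.warn("all-zero profile pair(s): distance defined as 0")
    d[~zero] = num[~zero] / den[~zero]
    return DistanceMatrix(squareform(d), ids=ids)


@dataclass
class PermanovaResult:
    """adonis-style output. ``alternative`` records the declared sidedness;
    the permutation test itself is the standard upper tail of pseudo-F."""

    r2: float
    pseudo_f: float
    p: float
    n_perm: int
    n_samples: int
    n_groups: int
    alternative: str = "two-sided"


def _ss_partition(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from the Gower partition of squared distances."""
    n = len(d2)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(d: DistanceMatrix | np.ndarray, groups,
              n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the squared distances into among- and within-group sums of
    squares, computes pseudo-F and R^2, and estimates p by permuting labels:
    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)  (add-one estimator).
    """
    dm = d.data if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    groups = np.asarray(groups)
    n = len(dm)
    if len(groups) != n:
        raise ValueError("groups length must match distance matrix size")
    uniq, counts = np.unique(groups, return_counts=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least 2 groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    d2 = dm ** 2
    ss_total, ss_within = _ss_partition(d2, groups)
    ss_among = ss_total - ss_within
    df_among, df_within = a - 1, n - a
    f_obs = (ss_among / df_among) / (ss_within / df_within) if ss_within > 0 else np.inf
    r2 = ss_among / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    # one-hot permuted labels; within-SS via quadratic forms, vectorized
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    f_perm = np.empty(n_perm)
    for k, g in enumerate(uniq):
        base = groups == g
        masks = base[perms]  # (n_perm, n)
        q = np.einsum("pi,ij,pj->p", masks, d2, masks) / 2.0 / counts[k]
        f_perm = q if k == 0 else f_perm + q
    ssw_perm = f_perm
    ssa_perm = ss_total - ssw_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ssa_perm / df_among) / (ssw_perm / df_within)
    p = (1 + np.sum(f_perm >= f_obs)) / (n_perm + 1)
    return PermanovaResult(
        r2=float(r2), pseudo_f=float(f_obs), p=float(p),
        n_perm=n_perm, n_samples=n, n_groups=a,
    )


@dataclass
class PCAResult:
    """Reduced scores plus everything needed to project new points."""

    scores: np.ndarray                 # (n, m)
    loadings: np.ndarray               # (m, d)
    explained_variance_ratio: np.ndarray  # (m,)
    n_components: int
    _pca: PCA = field(repr=False)
    _scaler: StandardScaler | None = field(repr=False, default=None)

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._scaler is not None:
            X = self._scaler.transform(X)
        return self._pca.transform(X)[:, : self.n_components]


def pca_reduce(features: pd.DataFrame | np.ndarray, var_frac: float = 0.95,
               standardize: bool = True) -> PCAResult:
    """PCA keeping the smallest set of leading components whose cumulative
    explained variance reaches ``var_frac``."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 feature")
    if np.isnan(X).any():
        raise ValueError("missing values are not allowed in PCA input")
    if not 0 < var_frac <= 1:
        raise ValueError("var_frac must be in (0, 1]")
    scaler = None
    if standardize:
        scaler = StandardScaler()
        X = scaler.fit_transform(X)
    pca = PCA()
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    reached = np.flatnonzero(cum >= var_frac - 1e-12)
    m = int(reached[0]) + 1 if len(reached) else len(evr)
    if var_frac == 1.0:  # drop numerically degenerate trailing components
        m = int(np.sum(pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]))
        m = max(m, 1)
    return PCAResult(
        scores=scores[:, :m],
        loadings=pca.components_[:m],
        explained_variance_ratio=evr[:m],
        n_components=m,
        _pca=pca,
        _scaler=scaler,
    )


def compare_groups(values, labels) -> tuple[dict, pd.DataFrame]:
    """Kruskal-Wallis omnibus plus Dunn's pairwise z tests (Bonferroni) and
    Cohen's d. Pairs with adjusted p > 0.05 and |d| < 0.1 are flagged as not
    distinguishable.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts == 0):
        raise ValueError("empty group")
    groups = [values[labels == g] for g in uniq]

    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        h, p_omni = 0.0, 1.0
    else:
        h, p_omni = sps.kruskal(*groups)

    n = len(values)
    ranks = sps.rankdata(values)
    mean_ranks = {g: ranks[labels == g].mean() for g in uniq}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(uniq)), 2))
    rows = []
    for i, j in pairs:
        gi, gj = uniq[i], uniq[j]
        ni, nj = counts[i], counts[j]
        se = np.sqrt(var_base * (1 / ni + 1 / nj))
        z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
        p_raw = 2 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * len(pairs))
        xi, xj = groups[i], groups[j]
        pooled = np.sqrt(
            ((ni - 1) * xi.var(ddof=1) + (nj - 1) * xj.var(ddof=1)) / (ni + nj - 2)
        ) if ni + nj > 2 else 0.0
        diff = xi.mean() - xj.mean()
        d = diff / pooled if pooled > 0 else (0.0 if diff == 0 else np.inf * np.sign(diff))
        rows.append({
            "group_a": gi, "group_b": gj, "dunn_z": z,
            "p_adj": p_adj, "cohen_d": d,
            "not_distinguishable": bool(p_adj > 0.05 and abs(d) < 0.1),
        })
    omnibus = {"statistic": float(h), "p": float(p_omni),
               "n_groups": len(uniq), "n": n}
    return omnibus, pd.DataFrame(rows)
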