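"""Reduction of candidate bioclimatic variables to a non-collinear,
influential subset.

Variables are first grouped by single-linkage clustering on |Spearman r|
(members of a cluster are mutually reachable through correlations above the
cutoff, default 0.7), then scored by permutation importance under a
presence/background model; one representative per cluster survives and the
top-k by importance are selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.ensemble import GradientBoostingClassifier

__all__ = [
    "SelectionResult",
    "correlation_clusters",
    "permutation_importance",
    "select_variables",
    "fit_importance_model",
    "run_variable_selection",
]


@dataclass
class SelectionResult:
    clusters: dict[str, int]           # variable -> cluster id
    importance: dict[str, float]       # variable -> score in [0, 1]
    selected: list[str]                # ordered, most important first
    r_threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": v, "cluster": self.clusters[v],
                 "importance": self.importance.get(v, np.nan),
                 "selected": v in self.selected}
                for v in sorted(self.clusters)]
        return pd.DataFrame(rows)


def correlation_clusters(env_table: pd.DataFrame, r_threshold: float = 0.7
                         ) -> dict[str, int]:
    """Single-linkage grouping of variables with |Spearman r| >= threshold.

    Cluster ids are assigned deterministically in variable-code order
    (the cluster containing the alphabetically first variable gets id 1).
    Constant variables correlate with nothing and become singletons, with a
    warning.
    """
    env_table = pd.DataFrame(env_table)
    if env_table.shape[1] < 2 or env_table.shape[0] < 10:
        raise ValueError("need at least 2 variables and 10 rows")
    cols = sorted(env_table.columns)
    X = env_table[cols].to_numpy(dtype=float)
    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(f"constant variable(s) placed in singleton clusters: "
                      f"{[c for c, f in zip(cols, const) if f]}")
    with np.errstate(invalid="ignore"):
        rho = stats.spearmanr(X).statistic
    if np.isscalar(rho):  # two-variable case
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.nan_to_num(np.abs(np.asarray(rho)), nan=0.0)
    np.fill_diagonal(rho, 1.0)
    dist = 1.0 - rho
    Z = linkage(squareform(dist, checks=False), method="single")
    labels = fcluster(Z, t=1.0 - r_threshold, criterion="distance")
    # relabel in first-appearance order over sorted variable codes
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for c, lab in zip(cols, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[c] = remap[lab]
    return out


def fit_importance_model(env_table: pd.DataFrame, labels: np.ndarray,
                         seed: int = 0) -> BaseEstimator:
    """Boosted-tree presence/background model used to score influence."""
    model = GradientBoostingClassifier(n_estimators=100, max_depth=3,
                                       learning_rate=0.1, random_state=seed)
    model.fit(env_table.to_numpy(dtype=float), np.asarray(labels))
    return model


def _predict(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return np.asarray(model.predict(X), dtype=float)


def permutation_importance(model, env_table: pd.DataFrame, variable: str,
                           k: int = 10, seed: int | np.random.SeedSequence = 0
                           ) -> float:
    """1 - Pearson r between predictions on original vs permuted table.

    Averaged over ``k`` independent permutations of the one variable and
    clamped to [0, 1]; models with constant predictions score 0 by
    convention (nothing to destroy).
    """
    env_table = pd.DataFrame(env_table)
    if variable not in env_table.columns:
        raise ValueError(f"variable {variable!r} not in the environment table")
    rng = np.random.default_rng(seed)
    X = env_table.to_numpy(dtype=float)
    base = _predict(model, X)
    if np.std(base) == 0:
        return 0.0
    j = list(env_table.columns).index(variable)
    scores = []
    for _ in range(k):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        pred = _predict(model, Xp)
        if np.std(pred) == 0:
            scores.append(1.0)
            continue
        r = np.corrcoef(base, pred)[0, 1]
        scores.append(1.0 - r)
    return float(np.clip(np.mean(scores), 0.0, 1.0))


def select_variables(clusters: dict[str, int], importance: dict[str, float],
                     target_k: int = 5, r_threshold: float = 0.7
                     ) -> SelectionResult:
    """One representative per collinearity cluster, top-k by importance.

    Ties are broken by variable-code order.  If fewer clusters than
    ``target_k`` exist, all representatives are returned with a warning.
    """
    missing = [v for v in clusters if v not in importance]
    if missing:
        raise ValueError(f"importance missing for variables: {missing}")
    reps: dict[int, str] = {}
    for v in sorted(clusters):  # sorted => deterministic tie-break
        cid = clusters[v]
        if cid not in reps or importance[v] > importance[reps[cid]]:
            reps[cid] = v
    ranked = sorted(reps.values(), key=lambda v: (-importance[v], v))
    if len(ranked) < target_k:
        warnings.warn(f"only {len(ranked)} collinearity clusters; returning all representatives")
    selected = ranked[:target_k]
    return SelectionResult(clusters=dict(clusters), importance=dict(importance),
                           selected=selected, r_threshold=r_threshold)


def run_variable_selection(env_table: pd.DataFrame, labels: np.ndarray,
                           target_k: int = 5, r_threshold: float = 0.7,
                           k_permutations: int = 10, seed: int = 0
                           ) -> SelectionResult:
    """Cluster -> score -> select, in one call (labels: 1 presence, 0 background)."""
    clusters = correlation_clusters(env_table, r_threshold=r_threshold)
    model = fit_importance_model(env_table, labels, seed=seed)
    ss = np.random.SeedSequence(seed)
    imp = {
        v: permutation_importance(model, env_table, v, k=k_permutations, seed=s)
        for v, s in zip(sorted(env_table.columns), ss.spawn(env_table.shape[1]))
    }
    return select_variables(clusters, imp, target_k=target_k, r_threshold=r_threshold)
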