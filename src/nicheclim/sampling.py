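"""Presence filtering in environmental space and exterior pseudo-absences.

Two steps prepare presence-only data for model calibration: (1) an
environmental filter thins presences to one per cell of a 2-D PCA-space
grid, correcting survey-effort bias; (2) pseudo-absences are drawn
uniformly from background cells lying *outside* the convex hull of the
presence environments, so calibration contrasts occupied climates against
climates the species demonstrably does not occupy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "EnvironmentalFilter",
    "EnvHull",
    "build_env_hull",
    "PASet",
    "sample_pseudo_absences",
]


class EnvironmentalFilter(BaseEstimator, TransformerMixin):
    """Thin presences to one per occupied bin of a 2-D PCA grid.

    ``fit`` learns the (standardized) presence PCA and equal-width bin edges
    over the presence score extent; ``transform`` keeps one uniformly random
    presence (seeded) per occupied bin.  Applying a fitted filter to its own
    output is the identity: each surviving row already owns its bin.
    """

    def __init__(self, n_bins: int = 25, seed: int = 0):
        self.n_bins = n_bins
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None) -> "EnvironmentalFilter":
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("need at least 2 presences")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        self.variables_ = list(X.columns)
        vals = X.to_numpy(dtype=float)
        self.center_ = vals.mean(axis=0)
        scale = vals.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        Z = (vals - self.center_) / self.scale_
        self.pca_ = PCA(n_components=min(2, Z.shape[1]), svd_solver="full").fit(Z)
        S = self.pca_.transform(Z)
        edges = []
        for ax in range(S.shape[1]):
            lo, hi = S[:, ax].min(), S[:, ax].max()
            if hi <= lo:
                warnings.warn(f"degenerate PCA axis {ax}: single bin used")
                edges.append(np.array([lo - 0.5, lo + 0.5]))
            else:
                edges.append(np.linspace(lo, hi, self.n_bins + 1))
        self.bin_edges_ = edges
        return self

    def _bins(self, X: pd.DataFrame) -> np.ndarray:
        Z = (pd.DataFrame(X)[self.variables_].to_numpy(dtype=float) - self.center_) / self.scale_
        S = self.pca_.transform(Z)
        idx = np.zeros((len(S), S.shape[1]), dtype=int)
        for ax, edges in enumerate(self.bin_edges_):
            b = np.digitize(S[:, ax], edges[1:-1])
            idx[:, ax] = b
        return idx

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        bins = self._bins(X)
        rng = np.random.default_rng(self.seed)
        keep: list[int] = []
        order = {}
        for i, key in enumerate(map(tuple, bins)):
            order.setdefault(key, []).append(i)
        for key in sorted(order):
            members = order[key]
            keep.append(members[int(rng.integers(len(members)))])
        return X.iloc[sorted(keep)]

    def fit_transform(self, X: pd.DataFrame, y=None, **kw) -> pd.DataFrame:
        return self.fit(X).transform(X)


@dataclass
class EnvHull:
    """Convex hull of the occupied environmental space (standardized units).

    Membership: a point is inside iff every facet inequality
    ``normal . x + offset <= tol`` holds (boundary counts as inside).  For
    degenerate (affinely dependent) point sets the hull lives in the
    positive-variance PCA subspace and membership additionally requires the
    off-subspace residual to vanish.
    """

    dimension: int
    vertices: np.ndarray          # hull vertices, standardized coordinates
    equations: np.ndarray         # facets: [normal | offset]
    center: np.ndarray
    scale: np.ndarray
    variables: list[str]
    subspace: np.ndarray | None = None   # d x k projection for degenerate sets
    subspace_origin: np.ndarray | None = None
    tol: float = 1e-9

    def contains(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.variables].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.center) / self.scale
        if self.subspace is not None:
            rel = Z - self.subspace_origin
            proj = rel @ self.subspace
            resid = rel - proj @ self.subspace.T
            ok_plane = np.linalg.norm(resid, axis=1) <= 1e-6
            Z = proj
        else:
            ok_plane = np.ones(len(Z), dtype=bool)
        A, b = self.equations[:, :-1], self.equations[:, -1]
        inside = np.all(Z @ A.T + b <= self.tol, axis=1)
        return inside & ok_plane


def build_env_hull(presence_env: pd.DataFrame) -> EnvHull:
    """Convex hull of presence environments (standardized per variable).

    Degenerate point sets (affinely dependent, e.g. all on a line) fall
    back, with a warning, to a hull in the PCA subspace that carries
    variance.
    """
    presence_env = pd.DataFrame(presence_env)
    variables = list(presence_env.columns)
    X = presence_env.to_numpy(dtype=float)
    d = X.shape[1]
    if X.shape[0] < d + 1:
        raise ValueError(f"need at least {d + 1} presence points in {d}-D")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    try:
        hull = ConvexHull(Z)
        return EnvHull(dimension=d, vertices=Z[hull.vertices],
                       equations=hull.equations, center=center, scale=scale,
                       variables=variables)
    except QhullError:
        warnings.warn("degenerate presence cloud: building hull in reduced PCA subspace")
        origin = Z.mean(axis=0)
        rel = Z - origin
        U, s, Vt = np.linalg.svd(rel, full_matrices=False)
        keep = s > max(s.max(), 1.0) * 1e-8
        k = int(keep.sum())
        if k == 0:
            raise ValueError("all presence points identical; no hull exists")
        basis = Vt[:k].T  # d x k
        P = rel @ basis
        if k == 1:
            lo, hi = P.min(), P.max()
            eqs = np.array([[1.0, -hi], [-1.0, lo]])
            verts = np.array([[lo], [hi]])
        else:
            hull = ConvexHull(P)
            eqs = hull.equations
            verts = P[hull.vertices]
        return EnvHull(dimension=d, vertices=verts, equations=eqs,
                       center=center, scale=scale, variables=variables,
                       subspace=basis, subspace_origin=origin)


def hull_membership_oracle(points: np.ndarray, vertices: np.ndarray,
                           tol: float = 1e-9) -> np.ndarray:
    """Independent membership check by linear-programming feasibility:
    x is in conv(V) iff x is a convex combination of the vertices."""
    points = np.atleast_2d(points)
    V = np.asarray(vertices, dtype=float)
    n = V.shape[0]
    out = np.zeros(len(points), dtype=bool)
    for i, x in enumerate(points):
        A_eq = np.vstack([V.T, np.ones(n)])
        b_eq = np.append(x, 1.0)
        res = linprog(c=np.zeros(n), A_eq=A_eq, b_eq=b_eq,
                      bounds=[(0, None)] * n, method="highs")
        out[i] = bool(res.success) and (res.status == 0)
    return out


@dataclass
class PASet:
    """One presence / pseudo-absence calibration set."""

    set_id: int
    presences: pd.DataFrame
    pseudo_absences: pd.DataFrame
    seed: int

    def to_frame(self) -> pd.DataFrame:
        p = self.presences.copy()
        p["label"] = 1
        a = self.pseudo_absences.copy()
        a["label"] = 0
        out = pd.concat([p, a], ignore_index=True)
        out["set_id"] = self.set_id
        return out


def sample_pseudo_absences(background: pd.DataFrame, hull: EnvHull,
                           presences: pd.DataFrame, n_pa: int | None = None,
                           n_sets: int = 3, seed: int = 0) -> list[PASet]:
    """Draw ``n_sets`` uniform samples of background cells outside the hull.

    ``background`` must carry the hull's variables (plus any id/coordinate
    columns, which are passed through).  ``n_pa`` defaults to the number of
    presences (prevalence 0.5).  Raises with the eligible count when too few
    exterior cells exist.
    """
    background = pd.DataFrame(background)
    eligible = background.loc[~hull.contains(background)]
    if n_pa is None:
        n_pa = len(presences)
    if len(eligible) < n_pa:
        raise ValueError(f"only {len(eligible)} background cells outside the presence "
                         f"environmental hull; {n_pa} pseudo-absences requested")
    ss = np.random.SeedSequence(seed)
    sets = []
    for sid, child in enumerate(ss.spawn(n_sets)):
        rng = np.random.default_rng(child)
        pick = rng.choice(len(eligible), size=n_pa, replace=False)
        sets.append(PASet(set_id=sid, presences=presences.reset_index(drop=True),
                          pseudo_absences=eligible.iloc[sorted(pick)].reset_index(drop=True),
                          seed=int(child.generate_state(1)[0] % (2**31))))
    return sets
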