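"""Two-axis PCA environmental space and occupancy density grids.

Niche comparisons operate not in geography but in the plane of the first
two principal components of the pooled background climates of both ranges.
Occurrences and backgrounds are kernel-smoothed onto a shared R x R grid;
dividing occurrence density by background availability gives the
availability-corrected occupancy ``z`` (rescaled to max 1) and its
probability-normalized form ``p``, the quantity all overlap and dynamics
statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = ["EnvironmentalPca", "DensityGrid", "occurrence_density_grid"]


class EnvironmentalPca(BaseEstimator, TransformerMixin):
    """PCA of standardized environments, truncated to the first two axes.

    Calibrated on the pooled backgrounds of both ranges so native and
    invaded occupancies are projected into one common space.  Fitted
    attributes: ``loadings_`` (variables x 2), ``center_``, ``scale_``,
    ``inertia_`` (variance fraction per axis, axis 1 >= axis 2), and
    ``variables_``.
    """

    def __init__(self, n_axes: int = 2):
        self.n_axes = n_axes

    def fit(self, X: pd.DataFrame, y=None) -> "EnvironmentalPca":
        X = pd.DataFrame(X)
        if len(X) < 3:
            raise ValueError("need at least 3 background rows")
        if X.shape[1] < 2:
            raise ValueError("need at least 2 variables")
        stds = X.std(axis=0, ddof=0)
        zero = stds[stds == 0]
        if len(zero):
            raise ValueError(f"zero-variance variable(s): {list(zero.index)}")
        self.variables_ = list(X.columns)
        self.center_ = X.mean(axis=0).to_numpy()
        self.scale_ = stds.to_numpy()
        Z = (X.to_numpy() - self.center_) / self.scale_
        pca = PCA(n_components=self.n_axes, svd_solver="full")
        pca.fit(Z)
        self.loadings_ = pca.components_.T  # variables x axes
        self.inertia_ = pca.explained_variance_ratio_
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = [v for v in self.variables_ if v not in X.columns]
        if missing:
            raise ValueError(f"missing variables: {missing}")
        Z = (X[self.variables_].to_numpy() - self.center_) / self.scale_
        return Z @ self.loadings_


@dataclass
class DensityGrid:
    """Kernel-smoothed occupancy of an environmental plane.

    ``o``: occurrence density; ``e``: background availability density;
    ``avail``: cells with non-negligible availability (e at least
    ``avail_threshold`` of its max — the correction o/e is numerically
    meaningless in kernel-tail cells where e underflows);
    ``z``: availability-corrected occupancy o/e on available cells,
    rescaled to max 1 (0 where e = 0); ``p``: z normalized to sum 1.
    All grids are R x R over a shared extent (pooled background bounding
    box padded 10% per side).
    """

    R: int
    extent: tuple[float, float, float, float]  # x0, x1, y0, y1
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray
    p: np.ndarray
    avail: np.ndarray

    def occurrence_p(self) -> np.ndarray:
        """Uncorrected occupancy: occurrence density on available cells,
        normalized to sum 1 (the o-weighting alternative to ``p``)."""
        w = np.where(self.avail, self.o, 0.0)
        tot = w.sum()
        return w / tot if tot > 0 else w

    def support(self, mass_fraction: float) -> np.ndarray:
        """Smallest set of cells holding ``mass_fraction`` of total z mass
        (the density-quantile niche support, cf. 50%/100% niche contours)."""
        flat = np.sort(self.z.ravel())[::-1]
        cs = np.cumsum(flat)
        if cs[-1] <= 0:
            return np.zeros_like(self.z, dtype=bool)
        thr = flat[np.searchsorted(cs, mass_fraction * cs[-1])]
        return (self.z >= thr) & (self.z > 0)

    def to_csv(self, path: str | Path, which: str = "p") -> None:
        np.savetxt(path, getattr(self, which), delimiter=",")


def _silverman_sigma_cells(x: np.ndarray, cell: float) -> float:
    """Silverman's rule bandwidth for one axis, converted to grid cells."""
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    a = min(sd, iqr / 1.349) if iqr > 0 else sd
    if a == 0:
        a = max(abs(x).max(), 1.0) * 0.01
    h = 0.9 * a * n ** (-1.0 / 5.0)
    return max(h / cell, 1e-6)


def _kde_on_grid(scores: np.ndarray, extent, R: int) -> np.ndarray:
    """Binned Gaussian KDE: 2-D histogram blurred with per-axis Silverman sigma."""
    x0, x1, y0, y1 = extent
    xedges = np.linspace(x0, x1, R + 1)
    yedges = np.linspace(y0, y1, R + 1)
    h, _, _ = np.histogram2d(scores[:, 0], scores[:, 1], bins=[xedges, yedges])
    sx = _silverman_sigma_cells(scores[:, 0], (x1 - x0) / R)
    sy = _silverman_sigma_cells(scores[:, 1], (y1 - y0) / R)
    d = ndimage.gaussian_filter(h, sigma=(sx, sy), mode="constant")
    return d


def occurrence_density_grid(occ_scores: np.ndarray, background_scores: np.ndarray,
                            R: int = 100,
                            extent: tuple[float, float, float, float] | None = None,
                            pad: float = 0.10,
                            avail_threshold: float = 0.01,
                            background_density: np.ndarray | None = None) -> DensityGrid:
    """Availability-corrected occupancy grid in PCA space.

    The extent defaults to the background bounding box expanded ``pad`` per
    side (kernels are not truncated at the data edge).  Passing an explicit
    ``extent`` lets several grids share one geometry, which every grid-to-
    grid statistic requires.  ``avail_threshold`` (fraction of the maximum
    background density) marks environments as unavailable before the o/e
    correction: in kernel-tail cells e underflows and the raw ratio would
    concentrate all occupancy mass on a handful of spurious spikes.
    """
    occ_scores = np.asarray(occ_scores, dtype=float)
    background_scores = np.asarray(background_scores, dtype=float)
    if occ_scores.shape[0] < 5:
        raise ValueError("need at least 5 occurrences for a density grid")
    if R < 20:
        raise ValueError("R must be at least 20")
    if extent is None:
        x0, x1 = background_scores[:, 0].min(), background_scores[:, 0].max()
        y0, y1 = background_scores[:, 1].min(), background_scores[:, 1].max()
        dx, dy = (x1 - x0) * pad, (y1 - y0) * pad
        extent = (x0 - dx, x1 + dx, y0 - dy, y1 + dy)

    o = _kde_on_grid(occ_scores, extent, R)
    # the background density depends only on (background, extent, R); callers
    # looping over occurrence resamples can pass it precomputed
    e = background_density if background_density is not None else \
        _kde_on_grid(background_scores, extent, R)
    avail = e >= avail_threshold * e.max()
    z = np.zeros_like(o)
    z[avail] = o[avail] / e[avail]
    if z.max() > 0:
        z = z / z.max()
    total = z.sum()
    p = z / total if total > 0 else z.copy()
    return DensityGrid(R=R, extent=extent, o=o, e=e, z=z, p=p, avail=avail)
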