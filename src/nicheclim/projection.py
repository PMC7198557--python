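"""Binarization, GCM consensus, change mapping and area statistics.

Continuous favourability is discretized with the threshold that maximizes
the Sørensen index (2a / (2a + b + c)) on a 70% training split, scored on
the held-out 30%.  Future favourability is the per-cell mean over GCMs
(consensus), binarized with the current-climate threshold so current and
future maps are comparable.  The change map has four classes: 0 stays
unfavourable, 1 becomes unfavourable, 2 stays favourable, 3 newly
favourable; area percentages use cos-latitude cell weights by default
(geographic cells shrink poleward).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .ensemble import SplitSpec, make_splits
from .grids import GridMap

__all__ = [
    "sorensen_score",
    "optimal_threshold",
    "ThresholdResult",
    "gcm_consensus",
    "binarize",
    "change_map",
    "ChangeMap",
    "area_statistics",
    "AreaStats",
]

UNFAVOURABLE, BECOME_UNFAVOURABLE, MAINTAINED, NEWLY_FAVOURABLE = 0, 1, 2, 3


def sorensen_score(predicted: np.ndarray, labels: np.ndarray) -> float:
    """Sørensen index of a binary prediction against presence (1) /
    pseudo-absence (0) labels: 2a / (2a + b + c)."""
    predicted = np.asarray(predicted).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if predicted.shape != labels.shape:
        raise ValueError("prediction/label shapes differ")
    if not labels.any():
        raise ValueError("no presences in the evaluation labels")
    a = np.sum(predicted & labels)       # presences predicted favourable
    b = np.sum(predicted & ~labels)      # pseudo-absences predicted favourable
    c = np.sum(~predicted & labels)      # presences predicted unfavourable
    return float(2.0 * a / (2.0 * a + b + c))


@dataclass
class ThresholdResult:
    threshold: float
    sorensen_train: float
    sorensen_test: float
    counts: dict  # a, b, c on the test fraction

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def optimal_threshold(favourability: np.ndarray, labels: np.ndarray,
                      split: SplitSpec = SplitSpec(n_repeats=1), step: float = 0.001
                      ) -> ThresholdResult:
    """Sørensen-maximizing binarization threshold.

    Grid search over thresholds 0..1 at ``step`` on a stratified training
    fraction (favourable ⇔ favourability >= threshold; ties resolved to the
    lowest maximizing threshold), scored on the held-out fraction.
    """
    favourability = np.asarray(favourability, dtype=float)
    labels = np.asarray(labels)
    if len(favourability) < 10:
        raise ValueError("need at least 10 labelled points")
    if np.ptp(favourability) == 0:
        raise ValueError("degenerate favourability: all values identical")
    cal, ev = make_splits(len(labels), labels, split)[0]
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 6)
    f_cal, y_cal = favourability[cal], labels[cal]
    best_t, best_s = grid[0], -1.0
    for t in grid:
        s = sorensen_score(f_cal >= t, y_cal)
        if s > best_s + 1e-12:
            best_t, best_s = float(t), s
    pred_ev = favourability[ev] >= best_t
    y_ev = labels[ev].astype(bool)
    counts = {
        "a": int(np.sum(pred_ev & y_ev)),
        "b": int(np.sum(pred_ev & ~y_ev)),
        "c": int(np.sum(~pred_ev & y_ev)),
    }
    return ThresholdResult(threshold=best_t, sorensen_train=best_s,
                           sorensen_test=sorensen_score(pred_ev, y_ev),
                           counts=counts)


def _check_geometry(maps: list[GridMap]) -> None:
    g0 = maps[0].geometry
    for m in maps[1:]:
        if m.geometry != g0 or not np.array_equal(m.mask, maps[0].mask):
            raise ValueError("maps have mismatched geometry or mask")


def gcm_consensus(maps: list[GridMap]) -> GridMap:
    """Per-cell mean favourability across GCM projections."""
    if not maps:
        raise ValueError("need at least one map")
    _check_geometry(maps)
    stackd = np.stack([m.values for m in maps])
    values = np.full(maps[0].geometry.shape, np.nan)
    m = maps[0].mask
    values[m] = np.mean(stackd[:, m], axis=0)
    return GridMap(geometry=maps[0].geometry, values=values,
                   mask=maps[0].mask, name="consensus")


def binarize(fav_map: GridMap, threshold: float) -> GridMap:
    values = np.where(fav_map.values >= threshold, 1.0, 0.0)
    return GridMap(geometry=fav_map.geometry, values=values, mask=fav_map.mask,
                   name=f"{fav_map.name}_binary")


@dataclass
class ChangeMap:
    """Four-class current-vs-future change raster."""

    geometry: object
    classes: np.ndarray   # float array with codes 0..3, NaN on masked cells
    mask: np.ndarray

    def count(self, code: int) -> int:
        return int(np.nansum(self.classes[self.mask] == code))


def change_map(current: GridMap, future: GridMap) -> ChangeMap:
    """Classify each terrestrial cell by its current/future favourable state:
    (0,0)->0, (1,0)->1, (1,1)->2, (0,1)->3."""
    _check_geometry([current, future])
    cur = current.values >= 0.5
    fut = future.values >= 0.5
    classes = np.full(current.geometry.shape, np.nan)
    m = current.mask
    classes[m] = (np.where(cur, 1, 0) + 2 * np.where(fut, 1, 0))[m].astype(float)
    # encoding above: cur+2*fut gives (0,0)->0, (1,0)->1, (0,1)->2, (1,1)->3;
    # remap to the documented codes 1=become unfavourable, 2=maintained, 3=new
    remap = {0.0: 0.0, 1.0: 1.0, 2.0: 3.0, 3.0: 2.0}
    out = classes.copy()
    for k, v in remap.items():
        out[classes == k] = v
    return ChangeMap(geometry=current.geometry, classes=out, mask=current.mask.copy())


@dataclass
class AreaStats:
    percent_favourable: float | None
    percent_expansion: float | None
    percent_lost: float | None
    weighting: str

    def to_dict(self) -> dict:
        return asdict(self)


def _weights(geometry, mask: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "cos-latitude":
        w = np.cos(np.deg2rad(geometry.lat_centers()))[:, None]
        w = np.broadcast_to(w, mask.shape).copy()
    elif weighting == "cell-count":
        w = np.ones(mask.shape)
    else:
        raise ValueError("weighting must be 'cos-latitude' or 'cell-count'")
    w[~mask] = 0.0
    return w


def area_statistics(map_: GridMap | ChangeMap, weighting: str = "cos-latitude"
                    ) -> AreaStats:
    """Percent of terrestrial area favourable (binary map) or percent
    expansion/lost relative to the current favourable area (change map)."""
    mask = map_.mask
    if not mask.any():
        raise ValueError("no terrestrial cells")
    if isinstance(map_, ChangeMap):
        w = _weights(map_.geometry, mask, weighting)
        cls = map_.classes
        cur_fav = w[(cls == BECOME_UNFAVOURABLE) | (cls == MAINTAINED)].sum()
        new = w[cls == NEWLY_FAVOURABLE].sum()
        lost = w[cls == BECOME_UNFAVOURABLE].sum()
        if cur_fav <= 0:
            raise ValueError("no currently favourable area; expansion undefined")
        fut_fav = w[(cls == MAINTAINED) | (cls == NEWLY_FAVOURABLE)].sum()
        return AreaStats(
            percent_favourable=float(fut_fav / w.sum() * 100.0),
            percent_expansion=float(new / cur_fav * 100.0),
            percent_lost=float(lost / cur_fav * 100.0),
            weighting=weighting,
        )
    w = _weights(map_.geometry, mask, weighting)
    fav = w[np.nan_to_num(map_.values) >= 0.5].sum()
    return AreaStats(percent_favourable=float(fav / w.sum() * 100.0),
                     percent_expansion=None, percent_lost=None, weighting=weighting)
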