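"""Multi-technique favourability modelling with Boyce-index selection.

Each technique is a sklearn estimator mapping an environment vector to a
favourability score in [0, 1] (its positive-class probability).  Models are
calibrated on repeated stratified 70/30 splits of every
presence/pseudo-absence set, evaluated with the continuous Boyce index
against a background sample, and techniques whose mean Boyce exceeds a
threshold (default 0.7, strict) are retained; the ensemble favourability is
the arithmetic mean over all retained fitted members.

The required technique classes: GLM (additive logistic with quadratic
terms), GAM (spline-additive logistic), GBM (gradient-boosted trees), FDA
(discriminant on a spline basis) and MARS (forward-selected hinge basis);
ANN, CTA, RF and a MAXENT-like logistic model are optional adapters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grids import ClimateStack, GridMap

__all__ = [
    "SplitSpec",
    "REQUIRED_TECHNIQUES",
    "OPTIONAL_TECHNIQUES",
    "make_technique",
    "make_splits",
    "boyce_index",
    "retain_models",
    "ensemble_forecast",
    "EvaluationResult",
    "FittedTechnique",
    "EnsembleNicheModel",
]

REQUIRED_TECHNIQUES = ("GLM", "GAM", "GBM", "FDA", "MARS")
OPTIONAL_TECHNIQUES = ("ANN", "CTA", "RF", "MAXENT")


@dataclass(frozen=True)
class SplitSpec:
    """Repeated stratified calibration/evaluation splitting."""

    fraction: float = 0.7
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("calibration fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")


def make_splits(n_rows: int, labels: np.ndarray, spec: SplitSpec
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Index pairs (calibration, evaluation) for each repeat.

    Presences and pseudo-absences are split separately at the calibration
    fraction (floor rounding on the calibration side), so prevalence is
    preserved across repeats.
    """
    labels = np.asarray(labels)
    if n_rows < 10 or len(labels) != n_rows:
        raise ValueError("need at least 10 labelled rows")
    rng = np.random.default_rng(spec.seed)
    strata = [np.flatnonzero(labels == v) for v in np.unique(labels)]
    for s in strata:
        if s.size < 2:
            raise ValueError("every stratum needs at least 2 rows")
    splits = []
    for _ in range(spec.n_repeats):
        cal, ev = [], []
        for s in strata:
            perm = rng.permutation(s)
            n_cal = int(np.floor(spec.fraction * s.size))
            n_cal = min(max(n_cal, 1), s.size - 1)
            cal.append(perm[:n_cal])
            ev.append(perm[n_cal:])
        splits.append((np.sort(np.concatenate(cal)), np.sort(np.concatenate(ev))))
    return splits


# --------------------------------------------------------------------------
# techniques


def _append_squares(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.hstack([X, X**2])


class TemperedDiscriminant(BaseEstimator, ClassifierMixin):
    """Flexible discriminant on a spline basis with tempered scores.

    Raw LDA posteriors under the Gaussian model saturate at 0/1 for
    well-separated calibration data, piling predictions into ties that ruin
    rank-based evaluation; the favourability score is therefore a sigmoid
    of the discriminant axis scaled by the calibration-score spread, a
    monotone recalibration that keeps the ranking.
    """

    def __init__(self, n_knots: int = 5):
        self.n_knots = n_knots

    def fit(self, X, y):
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        self.pipe_ = Pipeline([
            ("scale", StandardScaler()),
            ("spline", SplineTransformer(n_knots=self.n_knots, degree=3)),
            ("lda", LinearDiscriminantAnalysis()),
        ]).fit(np.asarray(X, dtype=float), y)
        d = self.pipe_.decision_function(np.asarray(X, dtype=float))
        self.scale_ = max(float(np.std(d)), 1e-9)
        return self

    def predict_proba(self, X):
        from scipy.special import expit

        p = expit(self.pipe_.decision_function(np.asarray(X, dtype=float)) / self.scale_)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class HingeBasisClassifier(BaseEstimator, ClassifierMixin):
    """Adaptive-regression-spline classifier (MARS-style).

    Candidate basis functions are the hinge pairs max(0, x - t) /
    max(0, t - x) at per-feature quantile knots; the active terms are
    selected adaptively by an L1-penalized logistic fit on the normalized
    basis, giving a sparse piecewise-linear additive model with calibrated
    probabilities.
    """

    def __init__(self, n_knots: int = 7, C: float = 0.3, random_state: int = 0):
        self.n_knots = n_knots
        self.C = C
        self.random_state = random_state

    def _candidate_basis(self, X: np.ndarray) -> np.ndarray:
        feats = []
        for j, knot in self.knots_:
            h = X[:, j] - knot
            feats.append(np.maximum(h, 0.0)[:, None])
            feats.append(np.maximum(-h, 0.0)[:, None])
        return np.hstack(feats)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("calibration data contains a single class")
        qs = np.linspace(0.1, 0.9, self.n_knots)
        self.knots_ = [(j, float(k)) for j in range(X.shape[1])
                       for k in np.quantile(X[:, j], qs)]
        B = self._candidate_basis(X)
        self.norm_ = np.abs(B).max(axis=0)
        self.norm_[self.norm_ == 0] = 1.0
        self.logit_ = LogisticRegression(penalty="l1", solver="liblinear",
                                         C=self.C, max_iter=2000,
                                         random_state=self.random_state)
        self.logit_.fit(B / self.norm_, y)
        return self

    def predict_proba(self, X):
        B = self._candidate_basis(np.asarray(X, dtype=float))
        return self.logit_.predict_proba(B / self.norm_)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def make_technique(name: str, seed: int = 0) -> BaseEstimator:
    """Instantiate one modelling technique by its field code."""
    name = name.upper()
    scaler = StandardScaler()
    # presence vs exterior pseudo-absence data are typically separable, so
    # the parametric adapters carry deliberate shrinkage: saturated 0/1
    # scores collapse the rank information the Boyce evaluation relies on
    if name == "GLM":
        return Pipeline([("scale", scaler),
                         ("quad", FunctionTransformer(_append_squares)),
                         ("logit", LogisticRegression(max_iter=2000, C=0.05))])
    if name == "GAM":
        return Pipeline([("scale", scaler),
                         ("spline", SplineTransformer(n_knots=5, degree=3)),
                         ("logit", LogisticRegression(max_iter=2000, C=0.3))])
    if name == "GBM":
        return GradientBoostingClassifier(n_estimators=150, max_depth=2,
                                          learning_rate=0.03, subsample=0.8,
                                          min_samples_leaf=20, random_state=seed)
    if name == "FDA":
        return TemperedDiscriminant()
    if name == "MARS":
        return HingeBasisClassifier(random_state=seed)
    if name == "ANN":
        return Pipeline([("scale", scaler),
                         ("mlp", MLPClassifier(hidden_layer_sizes=(8,), max_iter=3000,
                                               random_state=seed))])
    if name == "CTA":
        return DecisionTreeClassifier(min_samples_leaf=10, random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=200, min_samples_leaf=3,
                                      random_state=seed)
    if name == "MAXENT":
        return Pipeline([("scale", scaler),
                         ("poly", PolynomialFeatures(degree=2, include_bias=False)),
                         ("logit", LogisticRegression(max_iter=3000, C=0.5))])
    supported = REQUIRED_TECHNIQUES + OPTIONAL_TECHNIQUES
    raise ValueError(f"unknown technique {name!r}; supported: {', '.join(supported)}")


@dataclass
class FittedTechnique:
    """A fitted technique honouring the env-vector -> [0, 1] contract."""

    name: str
    model: BaseEstimator
    set_id: int = 0
    repeat: int = 0

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        fav = self.model.predict_proba(X)[:, 1]
        return np.clip(fav, 0.0, 1.0)


def fit_technique(name: str, X_cal: np.ndarray, y_cal: np.ndarray,
                  seed: int = 0) -> FittedTechnique:
    y_cal = np.asarray(y_cal)
    if len(np.unique(y_cal)) < 2:
        raise ValueError("calibration data contains a single class")
    model = make_technique(name, seed=seed)
    model.fit(np.asarray(X_cal, dtype=float), y_cal)
    return FittedTechnique(name=name.upper(), model=model)


# --------------------------------------------------------------------------
# continuous Boyce index


def boyce_index(pred_presences: np.ndarray, pred_background: np.ndarray,
                n_windows: int = 101) -> float:
    """Continuous Boyce index in [-1, 1].

    A window of width (max-min)/10 of the background prediction range
    slides over ``n_windows`` equally spaced midpoints; each window's
    predicted-to-expected ratio F = (presence fraction inside)/(background
    fraction inside) is computed, windows without background are skipped and
    consecutive duplicate F values collapsed, and the index is the Spearman
    rank correlation of F with window order.  Degenerate inputs (all
    predictions identical, or fewer than 3 usable windows) return NaN as an
    explicit error flag.
    """
    pred_presences = np.asarray(pred_presences, dtype=float)
    pred_background = np.asarray(pred_background, dtype=float)
    if pred_background.size < 20:
        raise ValueError("need at least 20 background predictions")
    if pred_presences.size < 5:
        raise ValueError("need at least 5 presence predictions")
    lo, hi = pred_background.min(), pred_background.max()
    if hi <= lo:
        return float("nan")
    width = (hi - lo) / 10.0
    mids = np.linspace(lo + width / 2.0, hi - width / 2.0, n_windows)
    F = []
    for m in mids:
        a, b = m - width / 2.0, m + width / 2.0
        nb = np.sum((pred_background >= a) & (pred_background <= b))
        if nb == 0:
            continue
        npres = np.sum((pred_presences >= a) & (pred_presences <= b))
        F.append((npres / pred_presences.size) / (nb / pred_background.size))
    # collapse runs of identical F (standard continuous-Boyce construction)
    kept = [f for i, f in enumerate(F) if i == 0 or f != F[i - 1]]
    if len(kept) < 3 or len(set(kept)) < 2:
        return float("nan")
    rho = stats.spearmanr(np.arange(len(kept)), kept).statistic
    return float(rho)


@dataclass
class EvaluationResult:
    """Boyce scores per (technique, PA set, repeat) and the retained list."""

    table: pd.DataFrame               # columns: technique, set_id, repeat, boyce
    threshold: float = 0.7

    @property
    def means(self) -> dict[str, float]:
        return self.table.groupby("technique")["boyce"].mean().to_dict()

    @property
    def retained(self) -> list[str]:
        return retain_models(self.means, self.threshold)

    def summary(self) -> dict:
        return {"threshold": self.threshold,
                "mean_boyce": {k: float(v) for k, v in sorted(self.means.items())},
                "retained": self.retained}


def retain_models(mean_boyce: dict[str, float], threshold: float = 0.7) -> list[str]:
    """Techniques with mean Boyce strictly above threshold, best first."""
    kept = [(b, t) for t, b in mean_boyce.items() if np.isfinite(b) and b > threshold]
    if not kept:
        warnings.warn("no technique exceeds the Boyce retention threshold")
    return [t for b, t in sorted(kept, key=lambda x: (-x[0], x[1]))]


def ensemble_forecast(models: list[FittedTechnique], stack: ClimateStack,
                      variables: list[str]) -> GridMap:
    """Mean favourability of all ensemble members over the unmasked cells."""
    if not models:
        raise ValueError("ensemble requires at least one retained model")
    missing = [v for v in variables if v not in stack.layers]
    if missing:
        raise ValueError(f"stack is missing covariate(s): {missing}")
    rows, cols = stack.unmasked_cells()
    X = np.column_stack([stack.layers[v][rows, cols] for v in variables])
    fav = np.zeros(X.shape[0])
    for m in models:
        fav += m.predict(X)
    fav /= len(models)
    values = np.full(stack.geometry.shape, np.nan)
    values[rows, cols] = fav
    return GridMap(geometry=stack.geometry, values=values, mask=stack.mask,
                   name=f"favourability_{stack.period_tag}")


# --------------------------------------------------------------------------
# top-level estimator


class EnsembleNicheModel(BaseEstimator):
    """Ensemble favourability model with Boyce-based technique retention.

    fit(X, y) calibrates every technique on repeated stratified splits of
    the labelled rows (1 = presence, 0 = pseudo-absence), scores each fit
    with the continuous Boyce index on the evaluation presences against
    ``background`` predictions, and retains techniques whose mean Boyce
    strictly exceeds ``boyce_threshold``.  predict(X) returns the mean
    favourability of all retained members.

    Fitted attributes: ``evaluation_`` (:class:`EvaluationResult`),
    ``retained_``, ``members_`` (retained fitted techniques), ``variables_``.
    """

    def __init__(self, techniques: tuple[str, ...] = REQUIRED_TECHNIQUES,
                 split: SplitSpec = SplitSpec(), boyce_threshold: float = 0.7,
                 n_windows: int = 101, seed: int = 0):
        self.techniques = techniques
        self.split = split
        self.boyce_threshold = boyce_threshold
        self.n_windows = n_windows
        self.seed = seed

    def fit(self, X, y, background=None, set_ids=None):
        """X: env rows; y: 0/1 labels; background: env rows of available
        cells used as the Boyce reference (defaults to the pseudo-absence
        rows); set_ids: per-row presence/pseudo-absence set id (one set if
        omitted)."""
        X = pd.DataFrame(X)
        self.variables_ = list(X.columns)
        Xv = X.to_numpy(dtype=float)
        y = np.asarray(y)
        if set_ids is None:
            set_ids = np.zeros(len(y), dtype=int)
        set_ids = np.asarray(set_ids)
        if background is None:
            background = Xv[y == 0]
        else:
            background = pd.DataFrame(background)[self.variables_].to_numpy(dtype=float)

        rows = []
        all_members: list[FittedTechnique] = []
        for sid in np.unique(set_ids):
            sel = set_ids == sid
            Xs, ys = Xv[sel], y[sel]
            spec = SplitSpec(self.split.fraction, self.split.n_repeats,
                             seed=self.split.seed + int(sid) * 1009 + self.seed)
            for rep, (cal, ev) in enumerate(make_splits(len(ys), ys, spec)):
                for name in self.techniques:
                    ft = fit_technique(name, Xs[cal], ys[cal], seed=self.seed)
                    ft.set_id, ft.repeat = int(sid), rep
                    pres_ev = Xs[ev][ys[ev] == 1]
                    b = boyce_index(ft.predict(pres_ev), ft.predict(background),
                                    n_windows=self.n_windows)
                    rows.append({"technique": ft.name, "set_id": int(sid),
                                 "repeat": rep, "boyce": b})
                    all_members.append(ft)
        self.evaluation_ = EvaluationResult(pd.DataFrame(rows), threshold=self.boyce_threshold)
        self.retained_ = self.evaluation_.retained
        self.members_ = [m for m in all_members if m.name in self.retained_]
        return self

    def predict(self, X) -> np.ndarray:
        if not getattr(self, "members_", None):
            raise ValueError("no retained ensemble members; fit first (and check Boyce scores)")
        X = pd.DataFrame(X)[self.variables_].to_numpy(dtype=float)
        fav = np.zeros(len(X))
        for m in self.members_:
            fav += m.predict(X)
        return fav / len(self.members_)

    def predict_stack(self, stack: ClimateStack) -> GridMap:
        if not getattr(self, "members_", None):
            raise ValueError("no retained ensemble members")
        return ensemble_forecast(self.members_, stack, self.variables_)
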