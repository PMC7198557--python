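"""Virtual-species worlds with known climate, suitability and invasion history.

The generator builds a stack of spatially smooth, optionally collinear
"bioclimatic" layers, a true suitability surface assembled from unimodal /
sigmoidal response functions, and native vs invaded regions whose available
environments are restricted (or extended) so that the true niche-unfilling
and niche-expansion indices of the construction are known analytically.
Presence-only occurrence samples can be drawn with a controllable spatial
observer bias, giving every downstream stage (variable selection, niche
statistics, ensemble modelling, projection) a ground truth to be checked
against.

The defaults emulate the study system: suitability increases sigmoidally
with warm-quarter temperature (high above 20 deg C), is flat over a broad
plateau of diurnal temperature range (favourable below ~14 deg C), and
declines with cold-quarter precipitation (unfavourable above ~900 mm);
remaining variables are either collinear shadows of the drivers or inert
noise, and the invaded range is constructed with high unfilling and
near-zero expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ClimateStack, GridGeometry
from .occurrences import OccurrenceSet

__all__ = [
    "VariableSpec",
    "ResponseFunction",
    "SyntheticWorld",
    "generate_climate_grid",
    "true_suitability",
    "sample_occurrences",
    "make_invasion_scenario",
    "perturb_future",
    "default_variable_specs",
    "default_responses",
]

# mean-temperature layers receive additive warming; precipitation layers scale
WARMING_VARS = ("bio1", "bio10")
PRECIP_VARS = ("bio13", "bio19")


@dataclass(frozen=True)
class VariableSpec:
    """Recipe for one synthetic climate layer.

    ``trend`` picks the large-scale spatial structure ('warm_equator' decays
    quadratically with latitude, 'lat'/'lon' are linear gradients, 'none' is
    pure smoothed noise); ``trend_weight`` in [0, 1] balances trend against
    noise; ``smoothness`` is the Gaussian smoothing length in cells.
    ``correlate_with``/``correlation`` force a target Pearson correlation
    with a previously defined variable.
    """

    name: str
    vmin: float
    vmax: float
    trend: str = "none"
    trend_weight: float = 0.5
    smoothness: float = 5.0
    correlate_with: str | None = None
    correlation: float | None = None

    def __post_init__(self) -> None:
        if self.vmax <= self.vmin:
            raise ValueError(f"{self.name}: vmax must exceed vmin")
        if not 0.0 <= self.trend_weight <= 1.0:
            raise ValueError(f"{self.name}: trend_weight must be in [0, 1]")
        if self.correlation is not None and abs(self.correlation) > 1.0:
            raise ValueError(f"{self.name}: correlation target {self.correlation} is unattainable (|r| > 1)")


@dataclass(frozen=True)
class ResponseFunction:
    """Suitability response of the virtual species to one variable, in [0, 1].

    Shapes: ``logistic_increasing`` (params: x0 inflection, k slope),
    ``logistic_decreasing`` (same), ``plateau`` (params: lo, hi plateau
    bounds, k edge steepness) and ``gaussian`` (params: center, width).
    """

    variable: str
    shape: str
    params: dict = field(default_factory=dict)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        x = np.asarray(x, dtype=float)
        p = self.params
        if self.shape == "logistic_increasing":
            return expit(p.get("k", 1.0) * (x - p["x0"]))
        if self.shape == "logistic_decreasing":
            return expit(-p.get("k", 1.0) * (x - p["x0"]))
        if self.shape == "plateau":
            k = p.get("k", 1.0)
            up = expit(k * (x - p["lo"]))
            down = expit(-k * (x - p["hi"]))
            # renormalize so the plateau interior sits at 1
            return np.clip(up * down * 4.0, 0.0, 1.0)
        if self.shape == "gaussian":
            return np.exp(-0.5 * ((x - p["center"]) / p["width"]) ** 2)
        raise ValueError(f"unknown response shape {self.shape!r}")


def default_variable_specs() -> list[VariableSpec]:
    """Six-layer default world: three drivers, two collinear shadows, one inert."""
    # east/west halves must be environmentally exchangeable (invasion
    # scenarios compare them): no longitudinal trends, and short noise
    # correlation lengths so each half samples the full noise distribution
    return [
        VariableSpec("bio10", -5.0, 32.0, trend="warm_equator", trend_weight=0.85, smoothness=4.0),
        VariableSpec("bio1", -10.0, 28.0, trend="none", smoothness=3.0,
                     correlate_with="bio10", correlation=0.95),
        VariableSpec("bio2", 2.0, 20.0, trend="lat", trend_weight=0.5, smoothness=3.0),
        VariableSpec("bio7", 5.0, 45.0, trend="none", smoothness=3.0,
                     correlate_with="bio2", correlation=0.85),
        VariableSpec("bio13", 0.0, 800.0, trend="none", trend_weight=0.0, smoothness=2.5),
        VariableSpec("bio19", 0.0, 1400.0, trend="lat", trend_weight=0.6, smoothness=3.0),
    ]


def default_responses() -> list[ResponseFunction]:
    return [
        ResponseFunction("bio10", "logistic_increasing", {"x0": 18.0, "k": 0.35}),
        ResponseFunction("bio2", "plateau", {"lo": -2.0, "hi": 14.0, "k": 1.2}),
        ResponseFunction("bio19", "logistic_decreasing", {"x0": 900.0, "k": 0.012}),
    ]


def _smooth_noise(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma, mode="reflect")
    return z


def _standardize(a: np.ndarray) -> np.ndarray:
    s = a.std()
    if s == 0:
        return np.zeros_like(a)
    return (a - a.mean()) / s


def _trend_field(kind: str, shape: tuple[int, int]) -> np.ndarray:
    n_rows, n_cols = shape
    lat = np.linspace(-1.0, 1.0, n_rows)[:, None] * np.ones((1, n_cols))
    lon = np.linspace(-1.0, 1.0, n_cols)[None, :] * np.ones((n_rows, 1))
    if kind == "warm_equator":
        return -(lat ** 2)
    if kind == "lat":
        return lat
    if kind == "lon":
        return lon
    if kind == "none":
        return np.zeros(shape)
    raise ValueError(f"unknown trend kind {kind!r}")


def generate_climate_grid(
    n_rows: int,
    n_cols: int,
    variable_specs: list[VariableSpec] | None = None,
    seed: int | np.random.SeedSequence = 0,
    geometry: GridGeometry | None = None,
    mask: np.ndarray | None = None,
    period_tag: str = "current",
) -> ClimateStack:
    """Generate a stack of smooth, range-clipped, optionally collinear layers.

    Each layer is a standardized mixture of a low-order spatial trend and
    Gaussian-smoothed white noise, mapped linearly onto the spec's value
    range; correlation targets are enforced exactly on the standardized
    fields by orthogonalized mixing.  Reproducible per seed.
    """
    if n_rows < 10 or n_cols < 10:
        raise ValueError("grid must be at least 10 x 10")
    specs = variable_specs if variable_specs is not None else default_variable_specs()
    if len(specs) < 2:
        raise ValueError("at least two variables are required")
    rng = np.random.default_rng(seed)
    if geometry is None:
        geometry = GridGeometry(n_rows=n_rows, n_cols=n_cols, cell_size=1.0 / 12.0,
                                lon_min=0.0, lat_min=0.0)
    if geometry.shape != (n_rows, n_cols):
        raise ValueError("geometry shape must match n_rows/n_cols")

    std_fields: dict[str, np.ndarray] = {}
    layers: dict[str, np.ndarray] = {}
    for spec in specs:
        trend = _standardize(_trend_field(spec.trend, (n_rows, n_cols)))
        noise = _standardize(_smooth_noise((n_rows, n_cols), spec.smoothness, rng))
        w = spec.trend_weight
        base = _standardize(w * trend + (1.0 - w) * noise)
        if spec.correlate_with is not None:
            if spec.correlate_with not in std_fields:
                raise ValueError(f"{spec.name}: correlation source {spec.correlate_with!r} "
                                 "must be defined earlier in the spec list")
            r = float(spec.correlation if spec.correlation is not None else 0.9)
            src = std_fields[spec.correlate_with]
            # residualize so the achieved sample correlation is exactly r
            resid = _standardize(base - (base * src).mean() / max((src * src).mean(), 1e-12) * src)
            base = r * src + np.sqrt(max(0.0, 1.0 - r * r)) * resid
            base = _standardize(base)
        std_fields[spec.name] = base
        lo, hi = base.min(), base.max()
        scaled = spec.vmin + (base - lo) / (hi - lo) * (spec.vmax - spec.vmin)
        layers[spec.name] = np.clip(scaled, spec.vmin, spec.vmax)

    if mask is None:
        mask = np.ones((n_rows, n_cols), dtype=bool)
    return ClimateStack(geometry=geometry, layers=layers, mask=mask, period_tag=period_tag)


def true_suitability(stack: ClimateStack, responses: list[ResponseFunction]) -> np.ndarray:
    """Per-cell product of responses, rescaled to max 1 over unmasked cells."""
    suit = np.ones(stack.geometry.shape, dtype=float)
    for resp in responses:
        if resp.variable not in stack.layers:
            raise ValueError(f"response references variable {resp.variable!r} absent from stack")
        vals = resp(stack.layers[resp.variable])
        suit = suit * np.nan_to_num(vals, nan=0.0)
    suit[~stack.mask] = 0.0
    m = suit[stack.mask].max() if stack.mask.any() else 0.0
    if m > 0:
        suit = suit / m
    suit[~stack.mask] = 0.0
    return suit


@dataclass
class SyntheticWorld:
    """A fully known study system: climate, truth, regions and samples."""

    stack: ClimateStack
    responses: list[ResponseFunction]
    suitability: np.ndarray
    native_mask: np.ndarray
    invaded_mask: np.ndarray
    occurrences: OccurrenceSet
    seed: int
    future_stacks: dict[str, ClimateStack] = field(default_factory=dict)
    true_unfilling: float | None = None
    true_expansion: float | None = None

    def __post_init__(self) -> None:
        if (self.native_mask & self.invaded_mask).any():
            raise ValueError("native and invaded regions must be disjoint")


def _bias_field(shape: tuple[int, int], eligible: np.ndarray, n_hubs: int,
                hub_scale: float, rng: np.random.Generator) -> np.ndarray:
    """Observer-accessibility weight: kernels around random sampling hubs.

    A floor keeps every cell reachable (survey effort is concentrated, not
    exclusive): far-from-hub cells retain ~5% of the peak sampling weight.
    """
    rows, cols = np.nonzero(eligible)
    idx = rng.choice(rows.size, size=min(n_hubs, rows.size), replace=False)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    bias = np.zeros(shape)
    for k in idx:
        d2 = (rr - rows[k]) ** 2 + (cc - cols[k]) ** 2
        bias += np.exp(-0.5 * d2 / hub_scale**2)
    top = bias.max()
    bias = bias / top if top > 0 else np.ones(shape)
    return 0.05 + 0.95 * bias


def sample_occurrences(
    world: SyntheticWorld,
    n: int,
    region_mask: np.ndarray,
    bias_strength: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    range_label: str = "native",
    n_hubs: int = 8,
    hub_scale: float = 8.0,
    year: int = 2000,
) -> OccurrenceSet:
    """Draw presence cells without replacement, P(cell) ∝ suitability x bias.

    Zero-suitability cells are never drawn.  ``bias_strength`` = 0 gives
    unbiased suitability-proportional sampling; larger values concentrate
    records near random observer hubs, mimicking survey-effort bias.
    """
    rng = np.random.default_rng(seed)
    eligible = region_mask & world.stack.mask & (world.suitability > 0)
    rows, cols = np.nonzero(eligible)
    if rows.size < n:
        raise ValueError(f"only {rows.size} eligible cells for {n} requested presences")
    w = world.suitability[rows, cols].astype(float)
    if bias_strength > 0:
        bias = _bias_field(world.stack.geometry.shape, eligible, n_hubs, hub_scale, rng)
        w = w * np.power(np.maximum(bias[rows, cols], 1e-6), bias_strength)
    p = w / w.sum()
    pick = rng.choice(rows.size, size=n, replace=False, p=p)
    geom = world.stack.geometry
    recs = []
    for k in pick:
        lon, lat = geom.cell_center(int(rows[k]), int(cols[k]))
        recs.append({"species": "virtualis", "longitude": lon, "latitude": lat,
                     "year": year, "range": range_label, "source": "synthetic",
                     "row": int(rows[k]), "col": int(cols[k]), "n_records": 1})
    df = pd.DataFrame(recs)
    return OccurrenceSet(df, aggregated=True)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw = cw / cw[-1]
    return float(np.interp(q, cw, v))


def binned_dynamics(native_env: np.ndarray, native_w: np.ndarray,
                    invaded_env: np.ndarray, invaded_w: np.ndarray,
                    bins: int = 60, edges: list[np.ndarray] | None = None
                    ) -> tuple[float, float]:
    """(expansion, unfilling) from weighted 2-D histograms of occupied cells.

    This is the analytic ground truth of a constructed scenario: occupancy is
    the true-suitability-weighted mass over each region's cells, binned on
    the two driver variables; a bin is occupied when it holds positive mass.
    """
    if edges is None:
        both = np.vstack([native_env, invaded_env])
        edges = [np.linspace(both[:, k].min(), both[:, k].max() + 1e-9, bins + 1)
                 for k in range(2)]

    def occupancy(env: np.ndarray, w: np.ndarray) -> np.ndarray:
        # occupancy mass per bin: suitability-weighted cell density, i.e. the
        # expected occurrence density under suitability-proportional sampling
        mass, _, _ = np.histogram2d(env[:, 0], env[:, 1], bins=edges, weights=w)
        return mass / mass.sum()

    hn = occupancy(native_env, native_w)
    hi = occupancy(invaded_env, invaded_w)
    expansion = float(hi[hn <= 0].sum())
    unfilling = float(hn[hi <= 0].sum())
    return expansion, unfilling


def _make_land_mask(shape: tuple[int, int], sea_fraction: float,
                    rng: np.random.Generator) -> np.ndarray:
    f = _smooth_noise(shape, sigma=max(shape) / 12, rng=rng)
    thr = np.quantile(f, sea_fraction)
    return f >= thr


def make_invasion_scenario(
    unfilling_target: float = 0.5,
    expansion_target: float = 0.0,
    seed: int = 0,
    n_rows: int = 120,
    n_cols: int = 160,
    n_native: int = 450,
    n_invaded: int = 450,
    bias_strength: float = 0.0,
    sea_fraction: float = 0.25,
    variable_specs: list[VariableSpec] | None = None,
    responses: list[ResponseFunction] | None = None,
    with_future: bool = False,
    tolerance: float = 0.05,
) -> SyntheticWorld:
    """Build a world whose true unfilling/expansion match the targets.

    The grid is split into a western native region and an eastern invaded
    region.  Unfilling is induced by excluding from the invaded region the
    cells whose warm-quarter temperature falls below a cutoff; expansion by
    excluding from the native region the cells above an upper cutoff.  Both
    cutoffs are solved by bisection against the analytically computed
    (binned-histogram) dynamics indices, so the construction's true indices
    land within ``tolerance`` of the targets.
    """
    if not (0.0 <= unfilling_target < 1.0 and 0.0 <= expansion_target < 1.0):
        raise ValueError("targets must lie in [0, 1)")
    if unfilling_target + expansion_target > 0.85:
        raise ValueError("joint targets infeasible: unfilling + expansion too close to 1")

    ss = np.random.SeedSequence(seed)
    s_clim, s_mask, s_nat, s_inv = ss.spawn(4)
    rng_mask = np.random.default_rng(s_mask)

    mask = _make_land_mask((n_rows, n_cols), sea_fraction, rng_mask)
    stack = generate_climate_grid(n_rows, n_cols, variable_specs, seed=s_clim, mask=mask)
    responses = responses if responses is not None else default_responses()
    suit = true_suitability(stack, responses)

    half = n_cols // 2
    west = np.zeros((n_rows, n_cols), dtype=bool)
    west[:, :half] = True
    east = ~west
    driver, second = "bio10", "bio19"
    b10 = stack.layers[driver]
    env2 = stack.layers[second]

    # fixed global binning of the 2-D driver space: the same bins define both
    # invaded-cell eligibility and the analytic truth, so expansion is zero
    # by construction unless deliberately induced
    n_bins = 60
    land_r, land_c = np.nonzero(mask & (suit > 1e-6))
    if land_r.size < 100:
        raise ValueError("too few suitable terrestrial cells; enlarge the grid")
    edges = [
        np.linspace(np.nanmin(b10[mask]), np.nanmax(b10[mask]) + 1e-9, n_bins + 1),
        np.linspace(np.nanmin(env2[mask]), np.nanmax(env2[mask]) + 1e-9, n_bins + 1),
    ]

    def bin_ids(r: np.ndarray, c: np.ndarray) -> np.ndarray:
        i1 = np.clip(np.digitize(b10[r, c], edges[0]) - 1, 0, n_bins - 1)
        i2 = np.clip(np.digitize(env2[r, c], edges[1]) - 1, 0, n_bins - 1)
        return i1 * n_bins + i2

    def bins_of(region: np.ndarray) -> np.ndarray:
        r, c = np.nonzero(region & mask & (suit > 1e-6))
        out = np.zeros(n_bins * n_bins, dtype=bool)
        out[bin_ids(r, c)] = True
        return out

    # both regions are confined to environments available on either side, so
    # with no cutoffs the constructed niches coincide exactly
    shared_bins = bins_of(west) & bins_of(east)

    def region_env(region: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sel = region & mask & (suit > 1e-6)
        r, c = np.nonzero(sel)
        keep = shared_bins[bin_ids(r, c)]
        r, c = r[keep], c[keep]
        e = np.column_stack([b10[r, c], env2[r, c]])
        return e, suit[r, c]

    nat_env, nat_w = region_env(west)
    if nat_env.shape[0] < 50:
        raise ValueError("native region has too few suitable cells; enlarge the grid")

    def masks_for(c_low: float, c_high: float) -> tuple[np.ndarray, np.ndarray]:
        b = np.nan_to_num(b10, nan=-np.inf)
        nat_all = west & mask & (b <= c_high)
        nr, nc = np.nonzero(nat_all)
        keep_n = shared_bins[bin_ids(nr, nc)]
        nat = np.zeros_like(nat_all)
        nat[nr[keep_n], nc[keep_n]] = True
        # invaded cells must sit in environments the native range occupies,
        # except deliberately novel warm cells above the native cutoff
        onr, onc = np.nonzero(nat & (suit > 1e-6))
        occupied_bins = np.zeros(n_bins * n_bins, dtype=bool)
        occupied_bins[bin_ids(onr, onc)] = True
        inv_all = east & mask & (b >= c_low)
        ir, ic = np.nonzero(inv_all)
        keep = shared_bins[bin_ids(ir, ic)] & (
            occupied_bins[bin_ids(ir, ic)] | (b10[ir, ic] > c_high))
        inv = np.zeros_like(inv_all)
        inv[ir[keep], ic[keep]] = True
        return nat, inv

    def indices_for(c_low: float, c_high: float) -> tuple[float, float]:
        nat, inv = masks_for(c_low, c_high)
        ne, nw_ = region_env(nat)
        ie, iw_ = region_env(inv)
        if ne.shape[0] < 20 or ie.shape[0] < 20:
            return np.nan, np.nan
        return binned_dynamics(ne, nw_, ie, iw_, edges=edges)

    lo_b10 = float(np.nanmin(b10[mask])) if mask.any() else 0.0
    hi_b10 = float(np.nanmax(b10[mask]))

    # initial guesses from suitability-weighted quantiles of the native niche
    c_low = (_weighted_quantile(nat_env[:, 0], nat_w, unfilling_target)
             if unfilling_target > 0 else lo_b10 - 1.0)
    c_high = hi_b10 + 1.0

    def solve(target: float, which: str, c_low: float, c_high: float) -> float:
        """Bisection on one cutoff against the binned index."""
        if which == "unfilling":
            a, b = lo_b10, _weighted_quantile(nat_env[:, 0], nat_w, 0.9)
        else:
            a, b = _weighted_quantile(nat_env[:, 0], nat_w, 0.1), hi_b10
        for _ in range(40):
            m = 0.5 * (a + b)
            exp_, unf_ = (indices_for(m, c_high) if which == "unfilling"
                          else indices_for(c_low, m))
            val = unf_ if which == "unfilling" else exp_
            if not np.isfinite(val):
                # region collapsed; retreat toward the permissive end
                if which == "unfilling":
                    b = m
                else:
                    a = m
                continue
            if abs(val - target) <= tolerance / 4:
                return m
            if which == "unfilling":
                if val < target:
                    a = m
                else:
                    b = m
            else:
                if val < target:
                    b = m
                else:
                    a = m
        return 0.5 * (a + b)

    if unfilling_target > 0:
        c_low = solve(unfilling_target, "unfilling", c_low, c_high)
    if expansion_target > 0:
        c_high = solve(expansion_target, "expansion", c_low, c_high)
        if unfilling_target > 0:  # one refinement pass: cutoffs interact weakly
            c_low = solve(unfilling_target, "unfilling", c_low, c_high)

    native_mask, invaded_mask = masks_for(c_low, c_high)
    true_exp, true_unf = indices_for(c_low, c_high)
    if not np.isfinite(true_exp) or abs(true_unf - unfilling_target) > tolerance \
            or abs(true_exp - expansion_target) > tolerance:
        raise ValueError(
            f"could not construct scenario: achieved (expansion={true_exp:.3f}, "
            f"unfilling={true_unf:.3f}) vs targets ({expansion_target}, {unfilling_target})")

    world = SyntheticWorld(
        stack=stack, responses=responses, suitability=suit,
        native_mask=native_mask, invaded_mask=invaded_mask,
        occurrences=OccurrenceSet(pd.DataFrame(), aggregated=True), seed=seed,
        true_unfilling=true_unf, true_expansion=true_exp,
    )
    occ_nat = sample_occurrences(world, n_native, native_mask, bias_strength,
                                 seed=s_nat, range_label="native")
    occ_inv = sample_occurrences(world, n_invaded, invaded_mask, bias_strength,
                                 seed=s_inv, range_label="introduced")
    world.occurrences = OccurrenceSet(
        pd.concat([occ_nat.records, occ_inv.records], ignore_index=True), aggregated=True)

    if with_future:
        world.future_stacks = {
            spec_tag: perturb_future(stack, dt, pf, tag=spec_tag)
            for spec_tag, dt, pf in (("RCP2.6", 1.1, 1.02), ("RCP8.5", 2.4, 1.05))
        }
    return world


def perturb_future(stack: ClimateStack, warming: float, precip_factor: float,
                   tag: str = "future") -> ClimateStack:
    """Future stack: additive warming on mean-temperature layers, multiplicative
    scaling on precipitation layers; other layers unchanged."""
    layers = {}
    for name, layer in stack.layers.items():
        if name in WARMING_VARS:
            layers[name] = layer + warming
        elif name in PRECIP_VARS:
            layers[name] = layer * precip_factor
        else:
            layers[name] = layer.copy()
    return stack.with_layers(layers, period_tag=tag)
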