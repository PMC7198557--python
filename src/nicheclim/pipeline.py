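"""Configuration-driven orchestration of the full analysis.

Stages run in a fixed order — simulate (or ingest) -> variable selection ->
niche dynamics -> environmental filter / pseudo-absences -> fit & evaluate
-> ensemble -> threshold -> project -> change & area statistics — and every
stochastic stage consumes a sub-seed derived by stable hashing of
(master seed, stage name), so inserting a stage never scrambles the
randomness of the others.  All artifacts are written to the output
directory and listed in a manifest that is written last.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics as dyn
from .ensemble import EnsembleNicheModel, SplitSpec, REQUIRED_TECHNIQUES
from .envspace import EnvironmentalPca
from .grids import ClimateStack, GridMap, write_ascii_grid
from .projection import (area_statistics, binarize, change_map, gcm_consensus,
                         optimal_threshold)
from .sampling import EnvironmentalFilter, build_env_hull, sample_pseudo_absences
from .selection import run_variable_selection
from .synthetic import make_invasion_scenario, perturb_future, true_suitability

logger = logging.getLogger("nicheclim")

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "stage_seed"]

# per-GCM scaling of the RCP warming/precipitation deltas
GCM_FACTORS = {"CNRM-CM5": 0.85, "GISS-E2-R": 1.0, "MIROC-ESM-CHEM": 1.15}
RCP_DELTAS = {"RCP2.6": (1.1, 1.02), "RCP8.5": (2.4, 1.05)}


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable (master seed, stage name) -> sub-seed below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything a run needs; serializable to/from YAML."""

    seed: int = 0
    outdir: str = "results"
    # synthetic scenario (the built-in demo world)
    synthetic: bool = True
    unfilling_target: float = 0.5
    expansion_target: float = 0.0
    n_rows: int = 120
    n_cols: int = 160
    n_native: int = 450
    n_invaded: int = 450
    bias_strength: float = 1.0
    # real-data inputs (used when synthetic is False)
    occurrence_csv: str | None = None
    raster_dir: str | None = None
    # optional future rasters: {"<rcp>_<gcm>": directory of .asc layers}
    future_raster_dirs: dict | None = None
    min_year: int = 1950
    # background = terrestrial cells within each range's occurrence bounding
    # box expanded by this margin (degrees)
    bg_margin_deg: float = 2.0
    # variable selection
    target_k: int = 5
    r_threshold: float = 0.7
    # niche dynamics
    n_reps: int = 999
    grid_R: int = 100
    analogue_policy: str = "full"
    # sampling design
    n_bins: int = 25
    n_pa: int | None = None
    n_sets: int = 3
    # modelling
    techniques: tuple[str, ...] = REQUIRED_TECHNIQUES
    calibration_fraction: float = 0.7
    n_repeats: int = 3
    boyce_threshold: float = 0.7
    # scenarios
    rcps: tuple[str, ...] = ("RCP2.6", "RCP8.5")
    gcms: tuple[str, ...] = ("CNRM-CM5", "GISS-E2-R", "MIROC-ESM-CHEM")
    weighting: str = "cos-latitude"

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("occurrence_csv", "raster_dir"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"config field {name!r} missing or path does not exist")
        if self.analogue_policy not in ("full", "analogue"):
            raise ValueError("analogue_policy must be 'full' or 'analogue'")
        SplitSpec(self.calibration_fraction, self.n_repeats)  # validates itself

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for tup in ("techniques", "rcps", "gcms"):
            if tup in data and isinstance(data[tup], list):
                data[tup] = tuple(data[tup])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for tup in ("techniques", "rcps", "gcms"):
            d[tup] = list(d[tup])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class ResultBundle:
    """Handles to every artifact a run produced."""

    config: RunConfig
    outdir: Path
    selection: object = None
    comparison: object = None
    model: EnsembleNicheModel | None = None
    threshold: object = None
    current_map: GridMap | None = None
    future_maps: dict = field(default_factory=dict)
    change_maps: dict = field(default_factory=dict)
    area_stats: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _dump_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute every stage and write the artifact bundle to ``config.outdir``."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(config=config, outdir=out)
    manifest: dict[str, str] = {}
    t_start = time.time()

    def record(name: str, path: Path) -> None:
        manifest[name] = str(path.relative_to(out))

    # ---- stage: simulate / ingest -------------------------------------
    t0 = time.time()
    world = None
    if config.synthetic:
        world = make_invasion_scenario(
            unfilling_target=config.unfilling_target,
            expansion_target=config.expansion_target,
            seed=stage_seed(config.seed, "simulate"),
            n_rows=config.n_rows, n_cols=config.n_cols,
            n_native=config.n_native, n_invaded=config.n_invaded,
            bias_strength=config.bias_strength,
        )
        stack = world.stack
        occ = world.occurrences.records
        half = config.n_cols // 2
        west = np.zeros(stack.geometry.shape, dtype=bool)
        west[:, :half] = True
        bg_masks = {"native": west & stack.mask, "introduced": (~west) & stack.mask}
    else:
        from .grids import read_stack
        from .occurrences import aggregate_to_cells, read_occurrences

        stack = read_stack(config.raster_dir)
        raw = read_occurrences(config.occurrence_csv, min_year=config.min_year)
        agg = aggregate_to_cells(raw, stack.geometry)
        on_land = stack.mask[agg.records["row"], agg.records["col"]]
        occ = agg.records.loc[on_land].reset_index(drop=True)
        _dump_json(out / "filter_report.json",
                   {**raw.filter_report, "aggregated_cells": int(len(agg)),
                    "dropped_non_terrestrial": int((~on_land).sum())})
        record("filter_report", out / "filter_report.json")
        bg_masks = {}
        for label in ("native", "introduced"):
            sub = occ[occ["range"] == label]
            if len(sub) < 5:
                raise ValueError(f"too few {label} occurrences after ingestion")
            g = stack.geometry
            m = config.bg_margin_deg
            lats, lons = g.lat_centers(), None
            lon_c = g.lon_min + (np.arange(g.n_cols) + 0.5) * g.cell_size
            in_lat = (lats >= sub["latitude"].min() - m) & (lats <= sub["latitude"].max() + m)
            in_lon = (lon_c >= sub["longitude"].min() - m) & (lon_c <= sub["longitude"].max() + m)
            bg_masks[label] = np.outer(in_lat, in_lon) & stack.mask
    logger.info("ingest: %d native + %d invaded occurrences on %s grid (%.1fs)",
                (occ["range"] == "native").sum(), (occ["range"] == "introduced").sum(),
                stack.geometry.shape, time.time() - t0)

    def env_of_mask(m: np.ndarray) -> pd.DataFrame:
        r, c = np.nonzero(m)
        df = stack.env_table(r, c)
        df["row"], df["col"] = r, c
        return df

    def env_of_occ(sub: pd.DataFrame) -> pd.DataFrame:
        return stack.env_table(sub["row"].to_numpy(), sub["col"].to_numpy())

    # ---- stage: variable selection ------------------------------------
    t0 = time.time()
    rng_sel = np.random.default_rng(stage_seed(config.seed, "select"))
    bg_all = env_of_mask(stack.mask)
    n_bg = min(len(bg_all), 4 * len(occ))
    bg_sample = bg_all.iloc[sorted(rng_sel.choice(len(bg_all), n_bg, replace=False))]
    all_vars = stack.variables
    sel_table = pd.concat([env_of_occ(occ)[all_vars], bg_sample[all_vars]],
                          ignore_index=True)
    sel_labels = np.r_[np.ones(len(occ)), np.zeros(n_bg)]
    selection = run_variable_selection(sel_table, sel_labels,
                                       target_k=config.target_k,
                                       r_threshold=config.r_threshold,
                                       seed=stage_seed(config.seed, "select"))
    variables = selection.selected
    p = out / "selection_report.csv"
    selection.to_frame().to_csv(p, index=False)
    record("selection_report", p)
    bundle.selection = selection
    logger.info("select: %s (%.1fs)", variables, time.time() - t0)

    # ---- stage: niche dynamics ----------------------------------------
    t0 = time.time()
    pca = EnvironmentalPca().fit(pd.concat(
        [env_of_mask(bg_masks["native"])[variables],
         env_of_mask(bg_masks["introduced"])[variables]], ignore_index=True))
    occ_nat = occ[occ["range"] == "native"]
    occ_inv = occ[occ["range"] == "introduced"]
    comparison = dyn.compare_niches(
        pca.transform(env_of_occ(occ_nat)[variables]),
        pca.transform(env_of_occ(occ_inv)[variables]),
        pca.transform(env_of_mask(bg_masks["native"])[variables]),
        pca.transform(env_of_mask(bg_masks["introduced"])[variables]),
        n_reps=config.n_reps, seed=stage_seed(config.seed, "nichediff"),
        R=config.grid_R, analogue_policy=config.analogue_policy,
        inertia=(float(pca.inertia_[0]), float(pca.inertia_[1])))
    p = out / "niche_comparison.json"
    comparison.to_json(p)
    record("niche_comparison", p)
    bundle.comparison = comparison
    logger.info("nichediff: D=%.3f expansion=%.3f unfilling=%.3f (%.1fs)",
                comparison.D, comparison.expansion, comparison.unfilling, time.time() - t0)

    # ---- stage: environmental filter + pseudo-absences ----------------
    t0 = time.time()
    pres_env = env_of_occ(occ)[variables]
    filt = EnvironmentalFilter(n_bins=config.n_bins,
                               seed=stage_seed(config.seed, "filter"))
    pres_filtered = filt.fit_transform(pres_env)
    occ_filtered = occ.iloc[pres_filtered.index]
    hull = build_env_hull(pres_filtered)
    pa_sets = sample_pseudo_absences(bg_all[variables + ["row", "col"]], hull,
                                     presences=occ_filtered.join(pres_filtered)[
                                         variables + ["row", "col"]],
                                     n_pa=config.n_pa, n_sets=config.n_sets,
                                     seed=stage_seed(config.seed, "pa"))
    p = out / "pa_sets.csv"
    pd.concat([s.to_frame() for s in pa_sets], ignore_index=True).to_csv(p, index=False)
    record("pa_sets", p)
    logger.info("filter/pa: %d -> %d presences, %d PA sets x %d (%.1fs)",
                len(pres_env), len(pres_filtered), len(pa_sets),
                len(pa_sets[0].pseudo_absences), time.time() - t0)

    # ---- stage: fit / evaluate / ensemble -----------------------------
    t0 = time.time()
    frames = [s.to_frame() for s in pa_sets]
    data = pd.concat(frames, ignore_index=True)
    rng_bg = np.random.default_rng(stage_seed(config.seed, "boyce_bg"))
    n_eval_bg = min(len(bg_all), 5000)
    boyce_bg = bg_all.iloc[sorted(rng_bg.choice(len(bg_all), n_eval_bg, replace=False))][variables]
    model = EnsembleNicheModel(
        techniques=tuple(config.techniques),
        split=SplitSpec(config.calibration_fraction, config.n_repeats,
                        seed=stage_seed(config.seed, "split")),
        boyce_threshold=config.boyce_threshold,
        seed=stage_seed(config.seed, "fit"))
    model.fit(data[variables], data["label"].to_numpy(),
              background=boyce_bg, set_ids=data["set_id"].to_numpy())
    p = out / "evaluation.csv"
    model.evaluation_.table.to_csv(p, index=False)
    record("evaluation", p)
    p = out / "evaluation_summary.json"
    _dump_json(p, model.evaluation_.summary())
    record("evaluation_summary", p)
    bundle.model = model
    if not model.retained_:
        _dump_json(out / "manifest.json", manifest)
        raise RuntimeError("pipeline halted: no technique passed the Boyce threshold "
                           "(partial manifest written)")
    logger.info("fit: retained %s (%.1fs)", model.retained_, time.time() - t0)

    # ---- stage: threshold ---------------------------------------------
    fav_data = model.predict(data[variables])
    thr = optimal_threshold(fav_data, data["label"].to_numpy(),
                            split=SplitSpec(config.calibration_fraction, 1,
                                            seed=stage_seed(config.seed, "threshold")))
    p = out / "threshold.json"
    thr.to_json(p)
    record("threshold", p)
    bundle.threshold = thr

    # ---- stage: project ------------------------------------------------
    t0 = time.time()
    current = model.predict_stack(stack)
    write_ascii_grid(out / "favourability_current.asc", current.values, stack.geometry)
    record("favourability_current", out / "favourability_current.asc")
    bundle.current_map = current
    current_bin = binarize(current, thr.threshold)

    def future_stacks_for(rcp: str) -> list:
        if config.synthetic:
            dt, pf = RCP_DELTAS[rcp]
            return [perturb_future(stack, dt * GCM_FACTORS[g],
                                   1.0 + (pf - 1.0) * GCM_FACTORS[g], tag=f"{rcp}_{g}")
                    for g in config.gcms]
        from .grids import read_stack
        dirs = config.future_raster_dirs or {}
        found = [(tag, d) for tag, d in dirs.items() if tag.startswith(rcp)]
        return [read_stack(d, period_tag=tag) for tag, d in found]

    area = {"current": area_statistics(current_bin, weighting=config.weighting).to_dict()}
    for rcp in config.rcps:
        gcm_stacks = future_stacks_for(rcp)
        if not gcm_stacks:
            logger.warning("no future layers for %s; skipping scenario", rcp)
            continue
        gcm_maps = [model.predict_stack(s) for s in gcm_stacks]
        consensus = gcm_consensus(gcm_maps)
        consensus.name = f"favourability_{rcp}"
        fname = f"favourability_{rcp.replace('.', '')}.asc"
        write_ascii_grid(out / fname, consensus.values, stack.geometry)
        record(f"favourability_{rcp}", out / fname)
        bundle.future_maps[rcp] = consensus

        cmap = change_map(current_bin, binarize(consensus, thr.threshold))
        cname = f"change_{rcp.replace('.', '')}.asc"
        write_ascii_grid(out / cname, cmap.classes, stack.geometry)
        record(f"change_{rcp}", out / cname)
        bundle.change_maps[rcp] = cmap
        area[rcp] = area_statistics(cmap, weighting=config.weighting).to_dict()
    p = out / "area_stats.json"
    _dump_json(p, area)
    record("area_stats", p)
    bundle.area_stats = area
    logger.info("project/change: %s (%.1fs)", {k: round(v["percent_favourable"], 1)
                for k, v in area.items()}, time.time() - t0)

    # ---- config echo + manifest (manifest written last) ----------------
    config.to_yaml(out / "config_echo.yaml")
    record("config_echo", out / "config_echo.yaml")
    _dump_json(out / "manifest.json", manifest)
    bundle.manifest = manifest
    logger.info("pipeline complete in %.1fs; %d artifacts", time.time() - t_start,
                len(manifest))
    return bundle
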