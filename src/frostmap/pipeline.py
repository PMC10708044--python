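"""End-to-end monitoring pipeline.

Orchestrates the whole chain on raster stacks: NDVI computation, gap filling
and Savitzky-Golay smoothing per pixel; the multi-year average shape model;
the shape-model fit producing the frost-year reference stack; the SFDI
raster; SASC area-matched selection; severity and validation summaries.
Everything is driven by a :class:`PipelineConfig` (loadable from YAML) and
lands in a run directory; inputs are never modified, and a provenance block
(config hash, package version, per-stage parameters) is written alongside
the outputs so a run can be replayed.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import savgol_filter

from . import __version__
from .assess import accuracy_rate, sfdi_quantile_severity
from .curves import DailyCurve, compute_ndvi
from .io import (GridSpec, read_raster, read_stack, require_same_grid,
                 write_raster)
from .reference import (DEFAULT_BIAS, ShapeModelFit, SmfBounds, fit_smf,
                        smf_transform_stack)
from .sasc import (build_pixel_table, pixel_area_mu, score_pixels,
                   select_affected, selection_mask)
from .sfdi import FrostWindow, detect_frost_window, sfdi_raster

log = logging.getLogger("frostmap.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "fill_and_smooth_stack", "config_for_scene"]


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to replay a monitoring run.

    ``reference_year_stacks`` maps a year label to ``{"red": path, "nir":
    path}``; the frost year likewise.  ``frost_start`` is the meteorological
    frost onset date (ISO string or date); without it, onset is detected from
    the NDVI decline.  ``target_area_mu`` is the official affected-area
    statistic; without it the SASC stage is skipped and only the raw SFDI
    map is produced.
    """

    reference_year_stacks: dict[int, dict[str, str]]
    frost_year_stack: dict[str, str]
    crop_fraction_path: str
    out_dir: str
    frost_start: datetime.date | str | None = None
    target_area_mu: float | None = None
    sg_window: int = 7
    sg_polyorder: int = 2
    bias: float = DEFAULT_BIAS
    smf_bounds: SmfBounds = dataclasses.field(default_factory=SmfBounds)
    fit_mode: str = "region"  # or "pixel"
    clip_negative_terms: bool = False
    within_class: bool = False
    crop_threshold: float = 0.0
    min_decline_days: int = 2
    severity_quantiles: tuple[float, float] = (0.5, 0.85)

    def __post_init__(self) -> None:
        if isinstance(self.frost_start, str):
            self.frost_start = datetime.date.fromisoformat(self.frost_start)
        if self.fit_mode not in ("region", "pixel"):
            raise ValueError("fit_mode must be 'region' or 'pixel'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "smf_bounds" in raw:
            b = raw["smf_bounds"]
            raw["smf_bounds"] = SmfBounds(tuple(b["sx"]), tuple(b["sy"]), tuple(b["t0"]))
        if "severity_quantiles" in raw:
            raw["severity_quantiles"] = tuple(raw["severity_quantiles"])
        raw["reference_year_stacks"] = {
            int(k): v for k, v in raw["reference_year_stacks"].items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["smf_bounds"] = {"sx": list(self.smf_bounds.sx),
                           "sy": list(self.smf_bounds.sy),
                           "t0": list(self.smf_bounds.t0)}
        if isinstance(self.frost_start, datetime.date):
            d["frost_start"] = self.frost_start.isoformat()
        d["severity_quantiles"] = list(self.severity_quantiles)
        return d


@dataclasses.dataclass
class PipelineResult:
    """In-memory view of a completed run (files live in ``out_dir``)."""

    config: PipelineConfig
    grid: GridSpec
    window: FrostWindow
    fit: ShapeModelFit | None
    sfdi: np.ndarray
    scores: np.ndarray
    sasc_result: object | None
    mask: np.ndarray | None
    severity: np.ndarray | None
    validation: dict
    out_dir: Path


def fill_and_smooth_stack(ndvi_stack: np.ndarray, window: int = 7,
                          polyorder: int = 2) -> np.ndarray:
    """Gap-fill (linear in time, edges held) then SG-smooth a (T, R, C) stack.

    Pixels with no valid observation at all stay all-NaN.
    """
    stack = np.asarray(ndvi_stack, dtype=float).copy()
    t = np.arange(stack.shape[0])
    flat = stack.reshape(stack.shape[0], -1)
    bad_cols = np.flatnonzero(np.isnan(flat).any(axis=0))
    for j in bad_cols:
        col = flat[:, j]
        valid = np.isfinite(col)
        if not valid.any():
            continue
        flat[:, j] = np.interp(t, t[valid], col[valid])
    stack = flat.reshape(stack.shape)
    all_nan = np.isnan(stack).any(axis=0)
    smoothed = savgol_filter(np.where(np.isnan(stack), 0.0, stack),
                             window_length=window, polyorder=polyorder,
                             axis=0, mode="interp")
    smoothed[:, all_nan] = np.nan
    return smoothed


def _region_curve(stack: np.ndarray, mask: np.ndarray,
                  start_day: datetime.date) -> DailyCurve:
    # per-day median across crop pixels: robust to a minority of frosted
    # pixels contaminating the regional frost-year target
    vals = np.nanmedian(stack[:, mask], axis=1)
    return DailyCurve(start_day, vals)


def _load_year(paths: dict[str, str], sg_window: int, sg_polyorder: int):
    red, grid, dates, role_r = read_stack(paths["red"])
    nir, grid2, dates2, role_n = read_stack(paths["nir"])
    require_same_grid(grid, grid2, "red and nir stacks")
    if dates != dates2:
        raise ValueError("red and nir stacks have different date maps")
    if (role_r, role_n) != ("red", "nir"):
        raise ValueError(f"unexpected band roles: {role_r!r}, {role_n!r}")
    ndvi = compute_ndvi(red.astype(float), nir.astype(float))
    return fill_and_smooth_stack(ndvi, sg_window, sg_polyorder), grid, dates


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full monitoring chain and write the artifact bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage ndvi+smooth: %d reference years", len(config.reference_year_stacks))
    ref_stacks, grid, dates = {}, None, None
    for year, paths in sorted(config.reference_year_stacks.items()):
        stack, g, d = _load_year(paths, config.sg_window, config.sg_polyorder)
        if grid is None:
            grid, dates = g, d
        else:
            require_same_grid(grid, g, f"stacks of year {year}")
            if d != dates:
                raise ValueError(f"year {year} has a different date map")
        ref_stacks[year] = stack
    frost_stack, g, d = _load_year(config.frost_year_stack,
                                   config.sg_window, config.sg_polyorder)
    require_same_grid(grid, g, "frost-year stack")
    if d != dates:
        raise ValueError("frost year has a different date map")
    start_day = dates[0]

    crop_fraction, grid_cf, _ = read_raster(config.crop_fraction_path)
    crop_fraction = crop_fraction.astype(float)
    require_same_grid(grid, grid_cf, "crop fraction raster")
    crop_mask = crop_fraction > config.crop_threshold
    if not crop_mask.any():
        raise ValueError("crop mask is empty: no pixel exceeds the crop threshold")

    log.info("stage reference: multi-year average of %d years", len(ref_stacks))
    g_stack = np.mean(np.stack(list(ref_stacks.values())), axis=0)

    g_region = _region_curve(g_stack, crop_mask, start_day)
    target_region = _region_curve(frost_stack, crop_mask, start_day)

    # the reference is a no-frost counterfactual: when the meteorological
    # onset is known, days from onset to the shape model's peak are frost
    # contaminated and carry zero weight in the fit
    fit_weights = np.ones(len(g_region))
    if config.frost_start is not None:
        onset_idx = g_region.index_of(config.frost_start)
        fit_weights[onset_idx:int(np.argmax(g_region.values)) + 1] = 0.0

    fit = fit_smf(g_region, target_region, config.bias, fit_weights,
                  bounds=config.smf_bounds)
    log.info("stage fit-reference (%s): sx=%.4f sy=%.4f t0=%.2f wrmse=%.5f",
             config.fit_mode, fit.sx, fit.sy, fit.t0, fit.objective)

    if config.fit_mode == "region":
        reference_stack = smf_transform_stack(g_stack, fit.sx, fit.sy, fit.t0,
                                              config.bias)
    else:  # per-pixel fit; expensive, meant for small windows
        reference_stack = np.full_like(g_stack, np.nan)
        for r, c in zip(*np.nonzero(crop_mask)):
            pf = fit_smf(DailyCurve(start_day, g_stack[:, r, c]),
                         DailyCurve(start_day, frost_stack[:, r, c]),
                         config.bias, fit_weights, bounds=config.smf_bounds)
            reference_stack[:, r, c] = pf.h.values

    reference_region = DailyCurve(start_day, fit.h.values)
    met_start = config.frost_start
    window = detect_frost_window(reference_region, target_region, met_start,
                                 min_decline_days=config.min_decline_days)
    log.info("stage window: days [%d, %d] (1-based [%d, %d], source %s)",
             window.sf_begin, window.sf_end, window.sf_begin + 1,
             window.sf_end + 1, window.source.value)

    sfdi = sfdi_raster(reference_stack, frost_stack, window, crop_mask,
                       clip_negative_terms=config.clip_negative_terms)
    scores = score_pixels(sfdi)

    area = pixel_area_mu(grid, latitude=None if not grid.is_geographic else
                         grid.origin_y - grid.pixel_height * sfdi.shape[0] / 2)
    validation: dict = {"window": {"sf_begin": window.sf_begin,
                                   "sf_end": window.sf_end,
                                   "source": window.source.value},
                        "pixel_area_mu": area}
    sasc_result = mask = severity = None
    if config.target_area_mu is None:
        warnings.warn("no target area configured: SASC skipped, writing raw "
                      "SFDI map only", stacklevel=2)
    else:
        table = build_pixel_table(sfdi, crop_fraction, area)
        sasc_result, table = select_affected(table, config.target_area_mu,
                                             within_class=config.within_class)
        mask = selection_mask(table, sfdi.shape)
        severity = sfdi_quantile_severity(sfdi, mask.astype(bool),
                                          config.severity_quantiles)
        validation["sasc"] = dataclasses.asdict(sasc_result)
        validation["accuracy_rate_pct"] = accuracy_rate(
            config.target_area_mu, sasc_result.selected_area) \
            if sasc_result.selected_area > 0 else None
        per_class = (table[table["score"] >= 1]
                     .assign(area=lambda x: x.crop_fraction * x.pixel_area)
                     .groupby("score")["area"].sum().reset_index())
        per_class.to_csv(out / "per_class_area.csv", index=False)

    window_tags = {"sf_begin": window.sf_begin, "sf_end": window.sf_end,
                   "source": window.source.value}
    write_raster(out / "sfdi.tif", sfdi.astype(np.float32), grid, window_tags)
    write_raster(out / "score.tif", scores, grid, window_tags)
    if mask is not None:
        write_raster(out / "affected_mask.tif", mask, grid, window_tags)
        write_raster(out / "severity.tif", severity, grid)
    (out / "reference_fit.json").write_text(json.dumps(
        {k: v for k, v in fit.to_dict().items() if k != "h"}
        | {"fit_mode": config.fit_mode}, indent=2))
    (out / "window.json").write_text(json.dumps(window_tags, indent=2))
    if sasc_result is not None:
        (out / "sasc_result.json").write_text(
            json.dumps(dataclasses.asdict(sasc_result), indent=2))
    (out / "validation.json").write_text(json.dumps(validation, indent=2))

    config_dict = config.to_dict()
    provenance = {
        "frostmap_version": __version__,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()).hexdigest(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return PipelineResult(config=config, grid=grid, window=window, fit=fit,
                          sfdi=sfdi, scores=scores, sasc_result=sasc_result,
                          mask=mask, severity=severity, validation=validation,
                          out_dir=out)


def config_for_scene(scene_dir: str | Path, out_dir: str | Path,
                     target_area_mu: float | None = None,
                     **overrides) -> PipelineConfig:
    """Build a config for a directory written by ``write_scene``.

    ``target_area_mu`` defaults to the scene's true affected area (the
    synthetic stand-in for the official statistic).
    """
    scene_dir = Path(scene_dir)
    meta = json.loads((scene_dir / "scene.json").read_text())
    if target_area_mu is None:
        target_area_mu = meta["true_affected_area_mu"]
    ref = {int(y): {"red": str(scene_dir / f"year_{y}_red.tif"),
                    "nir": str(scene_dir / f"year_{y}_nir.tif")}
           for y in meta["reference_years"]}
    fy = meta["frost_year"]
    return PipelineConfig(
        reference_year_stacks=ref,
        frost_year_stack={"red": str(scene_dir / f"year_{fy}_red.tif"),
                          "nir": str(scene_dir / f"year_{fy}_nir.tif")},
        crop_fraction_path=str(scene_dir / "crop_fraction.tif"),
        out_dir=str(out_dir),
        frost_start=meta["frost_onset_date"],
        target_area_mu=target_area_mu,
        **overrides)
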