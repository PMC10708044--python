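"""Synthetic frost scenes with known ground truth.

Everything downstream (smoothing, shape-model fitting, SFDI, SASC,
validation) is exercised on scenes built here, so no satellite download is
ever needed to test the pipeline.  A scene emulates a small window of daily
500 m NBAR-like imagery over one winter-wheat season (1 March - 31 May):

* per-pixel "normal" phenology: a double-logistic NDVI curve (green-up rise,
  grain-filling decline) with static per-pixel parameter variation standing
  in for soil, variety and management differences;
* inter-annual variability: each year applies a global scale-shift
  (time-scale, magnitude-scale, time-shift) drawn from small jitters — the
  same family of distortions the shape-model fit is designed to absorb;
* a frost event: on a random subset of pixels the frost-year curve is
  depressed by a dip profile (piecewise-linear "vee" by default) of known
  per-pixel depth, starting at a known onset day;
* observation defects: i.i.d. Gaussian NDVI noise and random missing days;
* sensor bands: NDVI is inverted to red/NIR reflectance through the fixed
  band model nir = c(1 + ndvi), red = c(1 - ndvi) with c = 0.25, so the NDVI
  computation recovers the simulated value exactly.

All randomness flows from one seed through ``numpy.random.default_rng``.
The truth object records the frost mask, per-pixel dip depth, crop fraction
and the exact crop-fraction-weighted affected area in mu.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import DailyCurve
from .io import GridSpec, write_raster, write_stack
from .reference import smf_transform_stack
from .sasc import pixel_area_mu

__all__ = [
    "PhenologyParams", "FrostInjection", "SceneTruth", "Scene",
    "make_reference_curve", "inject_frost", "simulate_scene", "write_scene",
    "SEASON_START", "SEASON_DAYS", "BAND_SCALE",
]

SEASON_START = datetime.date(2018, 3, 1)
SEASON_DAYS = 92  # 1 March - 31 May
BAND_SCALE = 0.25  # c in nir = c(1+ndvi), red = c(1-ndvi)


@dataclasses.dataclass(frozen=True)
class PhenologyParams:
    """Double-logistic NDVI phenology for a spring wheat canopy window.

    ``baseline`` is the late-winter NDVI level, ``amplitude`` the rise to the
    seasonal peak; ``greenup_day``/``senescence_day`` are the inflection days
    (0-based from 1 March) and the rates are logistic slopes in 1/day.  The
    defaults place the seasonal peak in late April / early May, after the
    early-April frost-sensitive elongation-booting stage.
    """

    baseline: float = 0.35
    amplitude: float = 0.45
    greenup_day: float = 18.0
    senescence_day: float = 80.0
    greenup_rate: float = 0.15
    senescence_rate: float = 0.12

    def __post_init__(self) -> None:
        if self.greenup_day >= self.senescence_day:
            raise ValueError("greenup_day must precede senescence_day")
        if self.amplitude <= 0 or self.greenup_rate <= 0 or self.senescence_rate <= 0:
            raise ValueError("amplitude and rates must be positive")


@dataclasses.dataclass(frozen=True)
class FrostInjection:
    """A frost dip: onset day, maximum NDVI drop, recovery duration, profile."""

    onset_day: int = 33  # 3 April for a 1 March anchor
    depth: float = 0.3
    recovery_days: int = 10
    profile: str = "linear_vee"  # or "exponential"

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be nonnegative")
        if self.recovery_days < 1:
            raise ValueError("recovery_days must be at least 1")
        if self.profile not in ("linear_vee", "exponential"):
            raise ValueError(f"unknown dip profile {self.profile!r}")

    def dip(self, days: np.ndarray) -> np.ndarray:
        """Dip magnitude (NDVI units, >= 0) at each day index.

        Zero at ``onset_day - 1``, reaching ``depth``, back to zero once
        ``recovery_days`` have elapsed.  The linear vee is a triangle whose
        daily sum is ``depth * recovery_days / 2`` up to discretisation.
        """
        t = np.asarray(days, dtype=float) - (self.onset_day - 1)
        if self.profile == "linear_vee":
            half = self.recovery_days / 2.0
            mag = self.depth * (1.0 - np.abs(t - half) / half)
        else:  # exponential: sharp drop then decay, truncated after recovery
            mag = np.where((t >= 1) & (t <= self.recovery_days),
                           self.depth * np.exp(-3.0 * (t - 1) / self.recovery_days),
                           0.0)
        return np.maximum(mag, 0.0)


@dataclasses.dataclass(frozen=True)
class SceneTruth:
    """Ground truth of a simulated scene."""

    frost_mask: np.ndarray       # bool (rows, cols)
    depth_field: np.ndarray      # NDVI drop per pixel, 0 where unaffected
    crop_fraction: np.ndarray    # [0, 1]
    seed: int
    true_affected_area: float    # mu, crop-fraction weighted over frost_mask
    pixel_area: float            # mu per pixel

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.indices(self.frost_mask.shape)
        return pd.DataFrame({
            "row": rows.ravel(), "col": cols.ravel(),
            "frost": self.frost_mask.ravel().astype(int),
            "depth": np.round(self.depth_field.ravel(), 10),
            "crop_fraction": np.round(self.crop_fraction.ravel(), 10),
        })


@dataclasses.dataclass(frozen=True)
class Scene:
    """A simulated multi-year scene, in memory.

    ``reference_years`` maps year label to an NDVI truth stack
    (days, rows, cols); ``frost_year`` is the frost-year NDVI stack with
    noise, gaps (NaN) and the injected dips.  ``red``/``nir`` reflectance
    stacks are derived views via the fixed band model.
    """

    grid: GridSpec
    start_day: datetime.date
    reference_years: dict[int, np.ndarray]
    frost_year_label: int
    frost_year: np.ndarray
    injection: FrostInjection
    truth: SceneTruth

    @property
    def dates(self) -> list[datetime.date]:
        n = self.frost_year.shape[0]
        return [self.start_day + datetime.timedelta(days=i) for i in range(n)]

    def bands(self, ndvi_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Invert an NDVI stack to (red, nir) reflectance stacks."""
        red = BAND_SCALE * (1.0 - ndvi_stack)
        nir = BAND_SCALE * (1.0 + ndvi_stack)
        return red, nir


def _double_logistic(days: np.ndarray, p: PhenologyParams) -> np.ndarray:
    up = 1.0 / (1.0 + np.exp(-p.greenup_rate * (days - p.greenup_day)))
    down = 1.0 / (1.0 + np.exp(-p.senescence_rate * (days - p.senescence_day)))
    return p.baseline + p.amplitude * (up - down)


def make_reference_curve(params: PhenologyParams = PhenologyParams(),
                         days: int = SEASON_DAYS,
                         start_day: datetime.date = SEASON_START) -> DailyCurve:
    """Sample the double-logistic phenology daily over the season window.

    The curve is unimodal by construction and bounded in
    [baseline, baseline + amplitude].
    """
    if days < 7:
        raise ValueError("season window must be at least one smoothing window long")
    t = np.arange(days, dtype=float)
    return DailyCurve(start_day, _double_logistic(t, params))


def inject_frost(curve: DailyCurve, inj: FrostInjection) -> DailyCurve:
    """Subtract the dip profile from a curve; output clamped to >= -1."""
    if not 0 <= inj.onset_day < len(curve):
        raise ValueError(f"onset day {inj.onset_day} outside the curve window")
    values = np.maximum(curve.values - inj.dip(curve.days), -1.0)
    return curve.with_values(values)


def simulate_scene(shape: tuple[int, int] = (24, 24),
                   frost_fraction: float = 0.3,
                   depth_range: tuple[float, float] = (0.25, 0.5),
                   noise_sd: float = 0.01,
                   gap_rate: float = 0.05,
                   seed: int = 0,
                   *,
                   n_reference_years: int = 3,
                   params: PhenologyParams = PhenologyParams(),
                   injection: FrostInjection = FrostInjection(),
                   grid: GridSpec = GridSpec(pixel_width=500.0, pixel_height=500.0),
                   year_sx_jitter: float = 0.02,
                   year_sy_jitter: float = 0.05,
                   year_t0_jitter: float = 2.0,
                   season_days: int = SEASON_DAYS,
                   start_day: datetime.date = SEASON_START) -> Scene:
    """Simulate a multi-year scene with a frost event of known truth.

    The defaults describe the emulated study conditions: a 24x24 window of
    500 m pixels, three frost-free reference years plus one frost year, 30%
    of pixels hit by a 3 April frost with NDVI dips of 0.25-0.5 recovering
    over 10 days, NDVI noise of 0.01 and 5% missing days.  ``depth`` of the
    ``injection`` argument is ignored; per-pixel depths are drawn uniformly
    from ``depth_range``.

    Reproducible: identical arguments and seed give identical scenes.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    t = np.arange(season_days, dtype=float)

    # static per-pixel phenology fields (soil/variety/management)
    baseline = params.baseline + rng.normal(0.0, 0.015, shape)
    amplitude = params.amplitude * (1.0 + rng.normal(0.0, 0.05, shape))
    greenup = params.greenup_day + rng.normal(0.0, 1.5, shape)
    senescence = params.senescence_day + rng.normal(0.0, 1.5, shape)

    up = 1.0 / (1.0 + np.exp(-params.greenup_rate
                             * (t[:, None, None] - greenup[None])))
    down = 1.0 / (1.0 + np.exp(-params.senescence_rate
                               * (t[:, None, None] - senescence[None])))
    base_stack = baseline[None] + amplitude[None] * (up - down)

    def year_effect() -> tuple[float, float, float]:
        return (1.0 + rng.uniform(-year_sx_jitter, year_sx_jitter),
                1.0 + rng.uniform(-year_sy_jitter, year_sy_jitter),
                rng.uniform(-year_t0_jitter, year_t0_jitter))

    def observe(stack: np.ndarray) -> np.ndarray:
        out = stack.copy()
        if noise_sd > 0:
            out += rng.normal(0.0, noise_sd, out.shape)
        if gap_rate > 0:
            out[rng.random(out.shape) < gap_rate] = np.nan
        return np.clip(out, -1.0, 1.0)

    first_year = start_day.year - n_reference_years
    reference_years = {}
    for k in range(n_reference_years):
        sx, sy, t0 = year_effect()
        reference_years[first_year + k] = observe(
            smf_transform_stack(base_stack, sx, sy, t0))

    # frost year: its own year effect, then dips on the frosted pixels
    sx, sy, t0 = year_effect()
    frost_stack = smf_transform_stack(base_stack, sx, sy, t0)
    frost_mask = rng.random(shape) < frost_fraction
    depth_field = np.where(
        frost_mask, rng.uniform(depth_range[0], depth_range[1], shape), 0.0)
    unit_dip = dataclasses.replace(injection, depth=1.0).dip(np.arange(season_days))
    frost_stack = frost_stack - unit_dip[:, None, None] * depth_field[None]
    frost_stack = observe(np.maximum(frost_stack, -1.0))

    crop_fraction = rng.beta(4.0, 2.0, shape)
    area = pixel_area_mu(grid, latitude=36.0 if grid.is_geographic else None)
    truth = SceneTruth(
        frost_mask=frost_mask,
        depth_field=depth_field,
        crop_fraction=crop_fraction,
        seed=seed,
        true_affected_area=float((frost_mask * crop_fraction).sum() * area),
        pixel_area=area,
    )
    return Scene(grid=grid, start_day=start_day, reference_years=reference_years,
                 frost_year_label=start_day.year, frost_year=frost_stack,
                 injection=injection, truth=truth)


def write_scene(scene: Scene, outdir: str | Path) -> Path:
    """Write a scene to disk: per-year red/NIR stacks, crop fraction, truth.

    Layout: ``year_<y>_red.tif`` / ``year_<y>_nir.tif`` (+ date-map CSVs),
    ``crop_fraction.tif``, ``truth_mask.tif``, ``truth.csv`` and
    ``scene.json`` (labels, frost onset, true area, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_years = dict(scene.reference_years)
    all_years[scene.frost_year_label] = scene.frost_year
    for year, ndvi in all_years.items():
        red, nir = scene.bands(ndvi)
        write_stack(outdir / f"year_{year}_red.tif", red.astype(np.float32),
                    scene.grid, scene.dates, "red")
        write_stack(outdir / f"year_{year}_nir.tif", nir.astype(np.float32),
                    scene.grid, scene.dates, "nir")
    write_raster(outdir / "crop_fraction.tif",
                 scene.truth.crop_fraction.astype(np.float32), scene.grid)
    write_raster(outdir / "truth_mask.tif",
                 scene.truth.frost_mask.astype(np.int8), scene.grid)
    scene.truth.to_frame().to_csv(outdir / "truth.csv", index=False)
    meta = {
        "start_day": scene.start_day.isoformat(),
        "season_days": scene.frost_year.shape[0],
        "reference_years": sorted(scene.reference_years),
        "frost_year": scene.frost_year_label,
        "frost_onset_day": scene.injection.onset_day,
        "frost_onset_date": (scene.start_day + datetime.timedelta(
            days=scene.injection.onset_day)).isoformat(),
        "seed": scene.truth.seed,
        "true_affected_area_mu": scene.truth.true_affected_area,
        "pixel_area_mu": scene.truth.pixel_area,
    }
    (outdir / "scene.json").write_text(json.dumps(meta, indent=2))
    return outdir
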