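"""Self-Adapting Statistics Correction (SASC).

Remote-sensing damage indices have no absolute severity scale, and mixed
pixels make any fixed SFDI threshold arbitrary.  SASC sidesteps both by
borrowing the one number the agricultural survey system does provide — the
official affected area — and letting it pick the threshold: pixels are
binned into integer scores (higher damage = lower score), then whole score
classes are accumulated in score order, each contributing its
crop-fraction-weighted area, until the cumulative mapped area most closely
matches the official statistic.

Score table: SFDI >= 16 scores 1; 15 <= SFDI < 16 scores 2; ... down to
1 <= SFDI < 2 scoring 16.  SFDI below 1 is unscored and treated as
non-affected.

Areas are in mu end-to-end (1 mu = 1/15 ha ~ 666.67 m^2; a 500 m pixel is
375 mu), the unit of Chinese agricultural statistics.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd

from .io import GridSpec

__all__ = [
    "MU_PER_M2", "M2_PER_MU", "SascResult",
    "score_pixels", "build_pixel_table", "select_affected", "pixel_area_mu",
    "mu_to_hectares", "hectares_to_mu",
]

M2_PER_MU = 1e4 / 15.0  # 666.666... m^2
MU_PER_M2 = 1.0 / M2_PER_MU

#: radius of the sphere used for geographic cell areas (the MODIS sphere), m
EARTH_RADIUS_M = 6_371_007.181

MAX_SCORE = 16
UNSCORED = 0


def mu_to_hectares(mu: float) -> float:
    return mu / 15.0


def hectares_to_mu(ha: float) -> float:
    return ha * 15.0


@dataclasses.dataclass(frozen=True)
class SascResult:
    """Outcome of the area-matched class selection."""

    selected_area: float
    target_area: float
    n_pixels_selected: int
    cutoff_score: int
    residual: float  # selected_area - target_area


def score_pixels(sfdi: np.ndarray) -> np.ndarray:
    """Map an SFDI raster to the integer score table.

    Returns an integer raster: 1 (most damaged) through 16, with 0 for
    unscored pixels (SFDI < 1 or nodata).
    """
    sfdi = np.asarray(sfdi, dtype=float)
    scores = np.full(sfdi.shape, UNSCORED, dtype=np.int16)
    with np.errstate(invalid="ignore"):
        in_bins = (sfdi >= 1.0) & (sfdi < 16.0)
        scores[in_bins] = (17 - np.floor(sfdi[in_bins])).astype(np.int16)
        scores[sfdi >= 16.0] = 1
    return scores


def build_pixel_table(sfdi: np.ndarray, crop_fraction: np.ndarray,
                      pixel_area: float | np.ndarray) -> pd.DataFrame:
    """Flatten co-registered rasters into the per-pixel SASC working table.

    Columns: row, col, sfdi, crop_fraction, pixel_area (mu), score, selected.
    Pixels with nodata SFDI or zero crop fraction are dropped (they can never
    contribute area).
    """
    sfdi = np.asarray(sfdi, dtype=float)
    crop_fraction = np.asarray(crop_fraction, dtype=float)
    if sfdi.shape != crop_fraction.shape:
        raise ValueError("sfdi and crop_fraction rasters have mismatched shapes")
    if np.nanmin(crop_fraction, initial=0.0) < 0 or np.nanmax(crop_fraction, initial=0.0) > 1:
        raise ValueError("crop_fraction must lie in [0, 1]")
    area = np.broadcast_to(np.asarray(pixel_area, dtype=float), sfdi.shape)
    rows, cols = np.indices(sfdi.shape)
    keep = np.isfinite(sfdi) & (crop_fraction > 0)
    table = pd.DataFrame({
        "row": rows[keep], "col": cols[keep],
        "sfdi": sfdi[keep],
        "crop_fraction": crop_fraction[keep],
        "pixel_area": area[keep],
    })
    table["score"] = score_pixels(table["sfdi"].to_numpy())
    table["selected"] = False
    return table


def select_affected(pixel_table: pd.DataFrame, target_area: float,
                    *, within_class: bool = False) -> tuple[SascResult, pd.DataFrame]:
    """Accumulate whole score classes until the mapped area matches the target.

    Classes are added in score order (1 first).  Among all whole-class
    cutoffs — including selecting nothing — the one whose cumulative
    crop-fraction-weighted area is nearest ``target_area`` wins; ties go to
    the smaller (more conservative) selection.  With ``within_class=True``
    the final class is refined pixel by pixel in descending-SFDI order while
    that improves the match.

    Returns the :class:`SascResult` and a copy of the table with its
    ``selected`` column filled.  Deterministic: no randomness anywhere.
    """
    if target_area <= 0:
        raise ValueError("target_area must be positive")
    table = pixel_table.copy()
    scored = table[table["score"] >= 1]
    if scored.empty:
        raise ValueError("no scored pixels (all SFDI < 1); nothing to select")
    contrib = scored["crop_fraction"] * scored["pixel_area"]
    class_area = contrib.groupby(scored["score"]).sum().sort_index()
    cum_area = class_area.cumsum()

    total = float(cum_area.iloc[-1])
    if total < target_area and not math.isclose(total, target_area, rel_tol=1e-6):
        warnings.warn(
            f"total scored area {total:.1f} mu is below the target "
            f"{target_area:.1f} mu; selecting all scored pixels", stacklevel=2)

    # candidate cutoffs: empty selection plus every whole-class prefix
    cutoffs = [0] + list(cum_area.index)
    areas = [0.0] + list(cum_area.to_numpy())
    best_i = min(range(len(cutoffs)),
                 key=lambda i: (abs(areas[i] - target_area), areas[i]))
    cutoff, sel_area = cutoffs[best_i], areas[best_i]

    selected = (table["score"] >= 1) & (table["score"] <= cutoff)

    if within_class and cutoff < MAX_SCORE:
        # consider extending into the next class pixel by pixel
        nxt = class_area.index[class_area.index > cutoff]
        if len(nxt):
            border = table.index[table["score"] == nxt[0]]
            order = table.loc[border, "sfdi"].sort_values(ascending=False).index
            for idx in order:
                add = table.at[idx, "crop_fraction"] * table.at[idx, "pixel_area"]
                if abs(sel_area + add - target_area) < abs(sel_area - target_area):
                    selected.at[idx] = True
                    sel_area += add
                else:
                    break

    table["selected"] = selected
    result = SascResult(
        selected_area=float(sel_area),
        target_area=float(target_area),
        n_pixels_selected=int(selected.sum()),
        cutoff_score=int(cutoff),
        residual=float(sel_area - target_area),
    )
    return result, table


def selection_mask(table: pd.DataFrame, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the ``selected`` column back onto the grid (1/0, int8)."""
    mask = np.zeros(shape, dtype=np.int8)
    sel = table[table["selected"]]
    mask[sel["row"].to_numpy(), sel["col"].to_numpy()] = 1
    return mask


def pixel_area_mu(grid: GridSpec, latitude: float | None = None) -> float:
    """Area of one raster cell in mu.

    Projected grids: plain width x height.  Geographic grids: the spherical
    zone formula R^2 * dlon * (sin(lat_top) - sin(lat_bottom)) for the cell
    centred at ``latitude`` (required), on the MODIS sphere.
    """
    w, h = abs(grid.pixel_width), abs(grid.pixel_height)
    if w == 0 or h == 0:
        raise ValueError("degenerate geotransform: zero pixel size")
    if grid.is_geographic:
        if latitude is None:
            raise ValueError("latitude is required for geographic grids")
        lat_top = math.radians(latitude + h / 2.0)
        lat_bot = math.radians(latitude - h / 2.0)
        area_m2 = EARTH_RADIUS_M ** 2 * math.radians(w) \
            * (math.sin(lat_top) - math.sin(lat_bot))
    else:
        area_m2 = w * h
    return area_m2 * MU_PER_M2
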