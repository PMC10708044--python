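"""Raster and table I/O.

Rasters are written as plain TIFF (via ``tifffile``) with a JSON sidecar
(``<name>.tif`` + ``<name>.json``) carrying the georeferencing: top-left
origin, pixel size, CRS kind (projected metres vs geographic degrees),
nodata value and free-form tags.  Reading returns the array together with a
:class:`GridSpec`; a write-then-read round trip preserves array, grid and
nodata exactly.

Multi-date stacks are (time, rows, cols) TIFFs with a date-map sidecar CSV
(columns ``band_index``, ``date``, ``band_role``) mapping band planes to
acquisition dates and roles (``red``/``nir``/``ndvi``).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridSpec", "write_raster", "read_raster",
    "write_stack", "read_stack", "read_yield_table",
    "read_curve_csv", "write_curve_csv",
]


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Georeferencing of a north-up raster grid.

    ``origin_x``/``origin_y`` locate the outer corner of the top-left pixel;
    ``pixel_width``/``pixel_height`` are positive cell sizes in CRS units
    (metres for ``crs='projected'``, degrees for ``crs='geographic'``); rows
    advance southward.
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_width: float = 500.0
    pixel_height: float = 500.0
    crs: str = "projected"
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        if self.crs not in ("projected", "geographic"):
            raise ValueError(f"crs must be 'projected' or 'geographic', got {self.crs!r}")
        if self.pixel_width <= 0 or self.pixel_height <= 0:
            raise ValueError("pixel sizes must be positive")

    @property
    def is_geographic(self) -> bool:
        return self.crs == "geographic"

    def matches(self, other: "GridSpec") -> bool:
        same = (self.crs == other.crs
                and np.isclose(self.origin_x, other.origin_x)
                and np.isclose(self.origin_y, other.origin_y)
                and np.isclose(self.pixel_width, other.pixel_width)
                and np.isclose(self.pixel_height, other.pixel_height))
        return bool(same)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if np.isnan(self.nodata):
            d["nodata"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        d = dict(d)
        if d.get("nodata") is None:
            d["nodata"] = float("nan")
        return cls(**{k: d[k] for k in
                      ("origin_x", "origin_y", "pixel_width", "pixel_height",
                       "crs", "nodata") if k in d})


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_raster(path: str | Path, array: np.ndarray, grid: GridSpec,
                 tags: dict | None = None) -> Path:
    """Write a raster (2-D) or stack (3-D, time-first) with its grid sidecar."""
    path = Path(path)
    array = np.asarray(array)
    if array.ndim not in (2, 3):
        raise ValueError("raster array must be 2-D or 3-D (time, rows, cols)")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, array)
    meta = {"grid": grid.to_dict(), "shape": list(array.shape),
            "dtype": str(array.dtype), "tags": tags or {}}
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, GridSpec, dict]:
    """Read a raster and its sidecar; returns (array, grid, tags)."""
    path = Path(path)
    array = tifffile.imread(path)
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        grid = GridSpec.from_dict(meta["grid"])
        tags = meta.get("tags", {})
    else:
        grid, tags = GridSpec(), {}
    return array, grid, tags


def require_same_grid(a: GridSpec, b: GridSpec, what: str = "rasters") -> None:
    if not a.matches(b):
        raise ValueError(f"{what} are not co-registered: {a.to_dict()} vs {b.to_dict()}")


def write_stack(path: str | Path, stack: np.ndarray, grid: GridSpec,
                dates: list[datetime.date], band_role: str,
                tags: dict | None = None) -> Path:
    """Write a (time, rows, cols) stack plus its date-map CSV."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (time, rows, cols)")
    if len(dates) != stack.shape[0]:
        raise ValueError("number of dates does not match stack depth")
    path = Path(path)
    write_raster(path, stack, grid, tags)
    pd.DataFrame({
        "band_index": np.arange(stack.shape[0]),
        "date": [d.isoformat() for d in dates],
        "band_role": band_role,
    }).to_csv(path.with_suffix(".csv"), index=False)
    return path


def read_stack(path: str | Path) -> tuple[np.ndarray, GridSpec, list[datetime.date], str]:
    """Read a stack and its date map; returns (stack, grid, dates, band_role)."""
    path = Path(path)
    stack, grid, _ = read_raster(path)
    datemap = pd.read_csv(path.with_suffix(".csv"))
    for col in ("band_index", "date", "band_role"):
        if col not in datemap.columns:
            raise ValueError(f"date map {path.with_suffix('.csv')} missing column: {col}")
    datemap = datemap.sort_values("band_index")
    dates = [datetime.date.fromisoformat(d) for d in datemap["date"]]
    roles = datemap["band_role"].unique()
    if len(roles) != 1:
        raise ValueError(f"stack {path} mixes band roles: {sorted(roles)}")
    if len(dates) != stack.shape[0]:
        raise ValueError("date map length does not match stack depth")
    return stack, grid, dates, str(roles[0])


YIELD_COLUMNS = ("unit_name", "year", "area", "production", "yield")


def read_yield_table(path: str | Path) -> pd.DataFrame:
    """Read a county-level yield CSV (unit_name, year, area, production, yield)."""
    table = pd.read_csv(path)
    missing = [c for c in YIELD_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"yield table {path} missing column(s): {missing}")
    return table


def read_curve_csv(path: str | Path):
    from .curves import DailyCurve
    return DailyCurve.from_frame(pd.read_csv(path))


def write_curve_csv(path: str | Path, curve) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curve.to_frame().to_csv(path, index=False)
    return path
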