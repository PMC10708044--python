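"""Daily NDVI time series: index computation, gap filling, Savitzky-Golay smoothing.

The monitoring season is a fixed daily window (canonically 1 March - 31 May);
index 0 of a :class:`DailyCurve` is its ``start_day``, index ``i`` is
``start_day + i`` days.  Report-facing layers label days 1-based, internals are
0-based throughout.
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = ["DailyCurve", "compute_ndvi", "fill_gaps", "sg_smooth"]


@dataclasses.dataclass(frozen=True)
class DailyCurve:
    """A regularly sampled (daily) NDVI series over one growing-season window.

    Parameters
    ----------
    start_day
        Calendar date anchoring index 0.
    values
        NDVI values, dimensionless, nominal range [-1, 1].  Invalid entries
        hold NaN.
    valid_mask
        Per-day observation validity.  Defaults to ``isfinite(values)``.
    """

    start_day: datetime.date
    values: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("DailyCurve values must be one-dimensional")
        mask = self.valid_mask
        if mask is None:
            mask = np.isfinite(values)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("valid_mask shape does not match values")
        object.__setattr__(self, "valid_mask", mask)

    def __len__(self) -> int:
        return self.values.size

    @property
    def days(self) -> np.ndarray:
        """0-based day indices of the window."""
        return np.arange(self.values.size)

    @property
    def dates(self) -> list[datetime.date]:
        return [self.start_day + datetime.timedelta(days=int(i)) for i in self.days]

    def index_of(self, date: datetime.date) -> int:
        """0-based index of a calendar date within the window."""
        i = (date - self.start_day).days
        if not 0 <= i < len(self):
            raise ValueError(f"{date} outside curve window starting {self.start_day}")
        return i

    def with_values(self, values: np.ndarray, valid_mask: np.ndarray | None = None) -> "DailyCurve":
        return DailyCurve(self.start_day, np.asarray(values, dtype=float),
                          self.valid_mask.copy() if valid_mask is None else valid_mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "ndvi": self.values, "valid": self.valid_mask})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DailyCurve":
        required = {"date", "ndvi", "valid"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"curve table missing column(s): {sorted(missing)}")
        dates = pd.to_datetime(frame["date"]).dt.date.to_numpy()
        if len(dates) == 0:
            raise ValueError("curve table is empty")
        deltas = np.array([(d - dates[0]).days for d in dates])
        if not np.array_equal(deltas, np.arange(len(dates))):
            raise ValueError("curve table dates are not a contiguous daily sequence")
        return cls(dates[0], frame["ndvi"].to_numpy(dtype=float),
                   frame["valid"].to_numpy(dtype=bool))


def compute_ndvi(red, nir, *, clamp: bool = True):
    """Normalized difference vegetation index ``(nir - red) / (nir + red)``.

    ``red`` is the red-band surface reflectance, ``nir`` the near-infrared
    band, both in [0, 1].  Invalid inputs (negative reflectance, non-finite, or
    a zero band sum) yield NaN rather than raising: in raster practice these
    are per-pixel data defects, not call errors.  Results outside [-1, 1] are
    clamped.

    Scalars in, scalar out; arrays in, array out (shapes must match).
    """
    red_arr = np.asarray(red, dtype=float)
    nir_arr = np.asarray(nir, dtype=float)
    if red_arr.shape != nir_arr.shape:
        raise ValueError("red and nir must have the same shape")
    denom = nir_arr + red_arr
    invalid = (~np.isfinite(red_arr)) | (~np.isfinite(nir_arr)) \
        | (red_arr < 0) | (nir_arr < 0) | (denom == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir_arr - red_arr) / denom
    ndvi = np.where(invalid, np.nan, ndvi)
    if clamp:
        ndvi = np.clip(ndvi, -1.0, 1.0)
    if np.isscalar(red) and np.isscalar(nir):
        return float(ndvi)
    return ndvi


def fill_gaps(curve: DailyCurve) -> DailyCurve:
    """Fill masked days by linear interpolation between the nearest valid days.

    Leading/trailing gaps are held at the nearest valid value.  The original
    ``valid_mask`` is preserved as metadata on the returned curve, so the
    provenance of interpolated days is not lost.  Idempotent.

    Raises ``ValueError`` when the curve has no valid observation at all
    (an unusable pixel).
    """
    valid = curve.valid_mask & np.isfinite(curve.values)
    if not valid.any():
        raise ValueError("cannot fill gaps: curve has no valid observations")
    if valid.all():
        return curve
    idx = np.flatnonzero(valid)
    filled = np.interp(curve.days, idx, curve.values[idx])
    return DailyCurve(curve.start_day, filled, curve.valid_mask.copy())


def sg_smooth(curve: DailyCurve, window: int = 7, polyorder: int = 2) -> DailyCurve:
    """Savitzky-Golay smoothing along the time axis.

    A least-squares polynomial of degree ``polyorder`` is fitted in each
    sliding window of ``window`` days and evaluated at the window centre.  The
    filter window of 7 days suits daily NDVI series, and degree 2 is the
    standard choice for phenology curves.  Edge values come from the
    polynomial fitted to the first/last full window, evaluated at the edge
    positions (``scipy`` ``mode='interp'``); no reflection padding, so the
    smoother reproduces polynomials up to degree ``polyorder`` exactly over
    the whole support.

    The curve must be gap-filled (all values finite) first.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window >= len(curve):
        raise ValueError(f"window {window} must be shorter than the series ({len(curve)})")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if not np.isfinite(curve.values).all():
        raise ValueError("sg_smooth requires a gap-filled curve (no NaN values)")
    smoothed = savgol_filter(curve.values, window_length=window, polyorder=polyorder,
                             mode="interp")
    return curve.with_values(smoothed)
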