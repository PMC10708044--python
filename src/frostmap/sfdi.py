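"""Spring Frost Damage Index (SFDI).

SFDI accumulates the daily gap between the reference NDVI curve (what the
crop would have done without frost) and the observed, smoothed frost-year
curve over the frost window:

    SFDI = sum_{i = sf_begin}^{sf_end} [ NDVI_ref(i) - NDVI_frost(i) ]

with inclusive bounds.  The window starts at frost onset — the date from the
meteorological record when available, otherwise the first sustained decline
of the observed curve — and ends where the reference curve peaks: past the
peak the crop enters grain filling, NDVI falls for physiological reasons and
frost damage can no longer be separated spectrally.

Daily terms where the observed curve sits *above* the reference are summed
as-is by default (the literal summation); ``clip_negative_terms=True`` floors
each daily term at zero instead, since the source method is silent on this.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum

import numpy as np

from .curves import DailyCurve

__all__ = [
    "WindowSource", "FrostWindow", "SfdiValue",
    "detect_frost_window", "compute_sfdi", "sfdi_raster",
]


class WindowSource(enum.Enum):
    MET_RECORD = "met_record"
    NDVI_DECLINE = "ndvi_decline"
    REFERENCE_PEAK = "reference_peak"


@dataclasses.dataclass(frozen=True)
class FrostWindow:
    """Inclusive day-index bounds of the SFDI summation.

    ``sf_begin``/``sf_end`` are 0-based indices into the season window;
    report layers print them 1-based.
    """

    sf_begin: int
    sf_end: int
    source: WindowSource = WindowSource.MET_RECORD

    def __post_init__(self) -> None:
        if not 0 <= self.sf_begin <= self.sf_end:
            raise ValueError(
                f"invalid frost window [{self.sf_begin}, {self.sf_end}]")

    @property
    def n_days(self) -> int:
        return self.sf_end - self.sf_begin + 1


@dataclasses.dataclass(frozen=True)
class SfdiValue:
    """Cumulative NDVI-day damage over a frost window (dimensionless * days)."""

    value: float
    n_days: int


def detect_frost_window(reference: DailyCurve, affected: DailyCurve,
                        met_start: datetime.date | int | None = None,
                        *, min_decline_days: int = 2,
                        decline_tol: float = 0.005) -> FrostWindow:
    """Locate the SFDI summation window.

    The start is the meteorological frost start date when given; otherwise the
    first day where the affected curve begins a sustained decline: a first
    difference below ``-decline_tol`` persisting at least ``min_decline_days``
    consecutive days.  The tolerance (NDVI/day) keeps residual noise in the
    smoothed curve from reading as onset; real frost dips fall an order of
    magnitude faster.  The end is the day the reference curve reaches its
    peak (earliest day on ties).

    Raises ``ValueError`` when no frost signal exists (no sustained decline
    and no met record) or when the reference peak precedes the start.
    """
    if len(reference) != len(affected) or reference.start_day != affected.start_day:
        raise ValueError("reference and affected curves must share the same grid")
    sf_end = int(np.argmax(reference.values))  # argmax takes the earliest max

    if met_start is not None:
        sf_begin = met_start if isinstance(met_start, (int, np.integer)) \
            else affected.index_of(met_start)
        source = WindowSource.MET_RECORD
    else:
        diffs = np.diff(affected.values)
        declining = diffs < -decline_tol
        run = 0
        sf_begin = None
        for i, d in enumerate(declining):
            run = run + 1 if d else 0
            if run >= min_decline_days:
                # first day observed below its predecessor (the day the
                # downward trend shows, not the pre-decline maximum)
                sf_begin = i - run + 2
                break
        if sf_begin is None:
            raise ValueError("no frost event detected: no sustained NDVI decline "
                             "and no meteorological start date")
        source = WindowSource.NDVI_DECLINE
    if sf_end < sf_begin:
        raise ValueError(
            f"reference peak (day {sf_end}) precedes frost start (day {sf_begin})")
    return FrostWindow(int(sf_begin), sf_end, source)


def compute_sfdi(reference: DailyCurve, affected: DailyCurve, window: FrostWindow,
                 *, clip_negative_terms: bool = False) -> SfdiValue:
    """Sum the daily reference-minus-affected NDVI gap over the frost window."""
    if len(reference) != len(affected) or reference.start_day != affected.start_day:
        raise ValueError("reference and affected curves must share the same grid")
    if window.sf_end >= len(reference):
        raise ValueError(f"frost window [{window.sf_begin}, {window.sf_end}] "
                         f"outside curve support (length {len(reference)})")
    sl = slice(window.sf_begin, window.sf_end + 1)
    terms = reference.values[sl] - affected.values[sl]
    if clip_negative_terms:
        terms = np.maximum(terms, 0.0)
    return SfdiValue(value=float(terms.sum()), n_days=window.n_days)


def sfdi_raster(reference_stack: np.ndarray, affected_stack: np.ndarray,
                window: FrostWindow, crop_mask: np.ndarray,
                *, clip_negative_terms: bool = False) -> np.ndarray:
    """Per-pixel SFDI over co-registered (time, rows, cols) NDVI stacks.

    ``crop_mask`` flags pixels carrying the crop; all other pixels get NaN
    (nodata).  The window is applied globally — in regional monitoring the
    frost onset comes from one meteorological record and the reference peak
    from the regional reference curve.
    """
    reference_stack = np.asarray(reference_stack, dtype=float)
    affected_stack = np.asarray(affected_stack, dtype=float)
    if reference_stack.shape != affected_stack.shape:
        raise ValueError("reference and affected stacks have mismatched shapes")
    if reference_stack.ndim != 3:
        raise ValueError("stacks must be (time, rows, cols)")
    crop_mask = np.asarray(crop_mask, dtype=bool)
    if crop_mask.shape != reference_stack.shape[1:]:
        raise ValueError("crop mask shape does not match the raster grid")
    if window.sf_end >= reference_stack.shape[0]:
        raise ValueError("frost window outside stack support")
    terms = (reference_stack - affected_stack)[window.sf_begin:window.sf_end + 1]
    if clip_negative_terms:
        terms = np.maximum(terms, 0.0)
    out = terms.sum(axis=0)
    out[~crop_mask] = np.nan
    return out
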