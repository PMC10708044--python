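"""Validation and severity assessment.

Accuracy of an area estimate is the ratio of the smaller to the larger of
the official and monitored affected areas, in percent — symmetric, scale
invariant, 100 when they agree.  Yield-based severity follows the national
freezing-damage bands: a reduction below 10% is mild, 10-30% medium, above
30% severe (official band wording leaves 10-11% unassigned; the affected-area
definition uses "more than 10%", so the boundary region goes to medium here;
both thresholds are configurable).
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AccuracyResult", "Severity", "RegressionResult",
    "accuracy_rate", "yield_reduction_rate", "classify_severity",
    "sfdi_covariate_regression", "yield_reduction_table", "sfdi_quantile_severity",
]


class Severity(enum.Enum):
    NONE = "none"
    MILD = "mild"
    MEDIUM = "medium"
    SEVERE = "severe"


@dataclasses.dataclass(frozen=True)
class AccuracyResult:
    area_official: float
    area_monitoring: float
    p: float  # percent


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int


def accuracy_rate(area_official: float, area_monitoring: float) -> float:
    """Agreement between official and monitored affected areas, percent.

    P = 100 * official / monitoring when the monitored area is the larger,
    and 100 * monitoring / official otherwise — i.e. 100 * min / max.
    """
    if area_official <= 0 or area_monitoring <= 0:
        raise ValueError("areas must be positive")
    lo, hi = sorted((area_official, area_monitoring))
    return 100.0 * (lo / hi)


def yield_reduction_rate(normal_mean: float, observed: float) -> float:
    """Percent yield loss relative to the non-disaster-year mean.

    Negative results (a yield gain) are reported as-is.
    """
    if normal_mean <= 0:
        raise ValueError("normal_mean yield must be positive")
    return 100.0 * (normal_mean - observed) / normal_mean


def classify_severity(reduction_rate: float,
                      mild_below: float = 10.0,
                      medium_upto: float = 30.0) -> Severity:
    """Severity class for a percent yield reduction.

    none for no loss; mild in (0, mild_below); medium in
    [mild_below, medium_upto]; severe above.
    """
    if not np.isfinite(reduction_rate):
        raise ValueError("reduction_rate must be finite")
    if reduction_rate <= 0:
        return Severity.NONE
    if reduction_rate < mild_below:
        return Severity.MILD
    if reduction_rate <= medium_upto:
        return Severity.MEDIUM
    return Severity.SEVERE


def sfdi_covariate_regression(unit_sfdi, covariate) -> RegressionResult:
    """OLS of a per-unit covariate (yield loss, minimum temperature, ...) on SFDI.

    Used to check that SFDI tracks the ground outcome across administrative
    units: slope, intercept, R^2 and the two-sided slope p-value.
    """
    x = np.asarray(unit_sfdi, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("unit_sfdi and covariate must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("regression needs at least 3 units")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("regression inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("SFDI has zero variance across units")
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            p_value=float(fit.pvalue), stderr=float(fit.stderr),
                            n=x.size)


def yield_reduction_table(yields: pd.DataFrame, disaster_year: int,
                          normal_years: list[int]) -> pd.DataFrame:
    """Per-unit yield reduction rates for a disaster year.

    ``yields`` has columns unit_name, year, yield (mass/area).  The baseline
    is the mean yield over the caller-specified ``normal_years`` (frost years
    must be excluded by the caller from meteorological records; nothing is
    inferred from the yields themselves).  Units missing either the disaster
    year or every normal year are dropped.
    """
    if disaster_year in normal_years:
        raise ValueError("disaster_year cannot be among normal_years")
    rows = []
    for unit, sub in yields.groupby("unit_name"):
        base = sub[sub["year"].isin(normal_years)]["yield"]
        this = sub[sub["year"] == disaster_year]["yield"]
        if base.empty or this.empty:
            continue
        normal_mean = float(base.mean())
        observed = float(this.iloc[0])
        rate = yield_reduction_rate(normal_mean, observed)
        rows.append({
            "unit_name": unit, "normal_mean_yield": normal_mean,
            "year_yield": observed, "reduction_rate": rate,
            "severity": classify_severity(rate).value,
        })
    return pd.DataFrame(rows, columns=["unit_name", "normal_mean_yield",
                                       "year_yield", "reduction_rate", "severity"])


def sfdi_quantile_severity(sfdi: np.ndarray, selected: np.ndarray,
                           quantiles: tuple[float, float] = (0.5, 0.85)) -> np.ndarray:
    """Relative severity map from SFDI quantiles among selected pixels.

    SFDI has no absolute severity scale, so this splits the *selected*
    (affected) pixels at the given SFDI quantiles into mild / medium / severe.
    It is an exploratory extension for map rendering, not a reproduction of
    any yield-based definition.  Returns int8: 0 unaffected, 1 mild,
    2 medium, 3 severe.
    """
    sfdi = np.asarray(sfdi, dtype=float)
    sel = np.asarray(selected, dtype=bool)
    out = np.zeros(sfdi.shape, dtype=np.int8)
    if not sel.any():
        return out
    q1, q2 = np.nanquantile(sfdi[sel], quantiles)
    out[sel] = 1
    out[sel & (sfdi >= q1)] = 2
    out[sel & (sfdi >= q2)] = 3
    return out
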