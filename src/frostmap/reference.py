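"""Reference NDVI curve construction by shape-model fitting (SMF).

A frost-year pixel has no observable "normal" trajectory, so the reference is
built in two steps: (1) average the NDVI curves of frost-free years into a
shape model ``g``; (2) geometrically rescale ``g`` onto the smoothed
frost-year curve,

    h(x) = sy * [ g(sx * (x + t0)) + bias ] - bias,

where ``sx`` (time scale) and ``t0`` (time shift, days) absorb phenological
differences between years, ``sy`` absorbs magnitude differences, and ``bias``
is a fixed crop-specific centring constant (0.61 for winter wheat).  The
typeset grouping of this transform is ambiguous in parts of the literature;
the form above, with bias added before and subtracted after the magnitude
scaling, is the one used by the shape-model-fitting lineage this follows and
makes ``bias`` a baseline-centring constant: with ``sy = 1`` the transform is
bias-independent.

Fitting minimises weighted RMSE over the bounded box sx in [0.9, 1.1],
sy in [0.5, 1.85], t0 in [-10, 10] by a deterministic coarse grid search
followed by bounded Nelder-Mead refinement; no randomness, so fits are
reproducible without seeds.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import minimize

from .curves import DailyCurve

__all__ = [
    "SmfBounds", "ShapeModelFit", "DEFAULT_BIAS",
    "multi_year_average", "smf_transform", "smf_transform_stack", "fit_smf",
]

DEFAULT_BIAS = 0.61  # winter wheat


@dataclasses.dataclass(frozen=True)
class SmfBounds:
    """Box constraints for the three scaling parameters."""

    sx: tuple[float, float] = (0.9, 1.1)
    sy: tuple[float, float] = (0.5, 1.85)
    t0: tuple[float, float] = (-10.0, 10.0)

    def contains(self, sx: float, sy: float, t0: float) -> bool:
        return (self.sx[0] <= sx <= self.sx[1]
                and self.sy[0] <= sy <= self.sy[1]
                and self.t0[0] <= t0 <= self.t0[1])


@dataclasses.dataclass(frozen=True)
class ShapeModelFit:
    """Result of fitting the shape model to a frost-year curve.

    ``g`` is the multi-year average (shape model), ``h`` the transformed
    reference curve on the same daily grid, ``objective`` the weighted RMSE
    at the optimum.
    """

    g: DailyCurve
    sx: float
    sy: float
    t0: float
    bias: float
    h: DailyCurve
    objective: float

    def to_dict(self) -> dict:
        return {
            "sx": self.sx, "sy": self.sy, "t0": self.t0,
            "bias": self.bias, "objective": self.objective,
            "h": self.h.values.tolist(),
        }


def multi_year_average(curves: list[DailyCurve]) -> DailyCurve:
    """Pointwise arithmetic mean of same-window curves from frost-free years."""
    if not curves:
        raise ValueError("multi_year_average needs at least one curve")
    n = len(curves[0])
    for c in curves[1:]:
        if len(c) != n:
            raise ValueError("curves have mismatched lengths")
        if c.start_day != curves[0].start_day:
            raise ValueError("curves have mismatched start days")
    stack = np.stack([c.values for c in curves])
    return DailyCurve(curves[0].start_day, stack.mean(axis=0))


def smf_transform(g: DailyCurve, sx: float, sy: float, t0: float,
                  bias: float = DEFAULT_BIAS, *,
                  bounds: SmfBounds | None = SmfBounds()) -> DailyCurve:
    """Apply the scale-shift transform to the shape model ``g``.

    Evaluated on the original daily grid; ``g`` at non-integer or
    out-of-window arguments is obtained by linear interpolation with
    constant extension beyond the window ends.  Parameters outside the
    standard box only warn (the transform itself is defined everywhere).
    """
    if bounds is not None and not bounds.contains(sx, sy, t0):
        warnings.warn(
            f"SMF parameters (sx={sx}, sy={sy}, t0={t0}) outside the standard box",
            stacklevel=2)
    x = g.days.astype(float)
    gv = np.interp(sx * (x + t0), x, g.values)  # np.interp clamps at the ends
    return DailyCurve(g.start_day, sy * (gv + bias) - bias)


def smf_transform_stack(stack: np.ndarray, sx: float, sy: float, t0: float,
                        bias: float = DEFAULT_BIAS) -> np.ndarray:
    """Apply the scale-shift transform along the time axis of a raster stack.

    ``stack`` is (days, rows, cols); the transform and its edge handling are
    identical to :func:`smf_transform` applied to every pixel's series.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (days, rows, cols)")
    n = stack.shape[0]
    args = np.clip(sx * (np.arange(n, dtype=float) + t0), 0, n - 1)
    i0 = np.floor(args).astype(int)
    i1 = np.minimum(i0 + 1, n - 1)
    frac = (args - i0)[:, None, None]
    warped = (1 - frac) * stack[i0] + frac * stack[i1]
    return sy * (warped + bias) - bias


def _wrmse(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    return float(np.sqrt(np.sum(w * (a - b) ** 2) / np.sum(w)))


def fit_smf(g: DailyCurve, target: DailyCurve, bias: float = DEFAULT_BIAS,
            weights: np.ndarray | None = None, *,
            bounds: SmfBounds = SmfBounds(),
            grid_steps: tuple[float, float, float] = (0.01, 0.05, 1.0)) -> ShapeModelFit:
    """Fit (sx, sy, t0) so the transformed shape model matches ``target``.

    Minimises weighted RMSE (uniform weights by default) by an exhaustive
    lattice search over the box at steps ``grid_steps`` = (sx, sy, t0),
    followed by bounded Nelder-Mead refinement from the best lattice point.
    Ties on the lattice break toward the identity (1, 1, 0), comparing
    |sx - 1| first, then |sy - 1|, then |t0|.  The refined point is accepted
    only if it does not worsen the objective, so the returned fit is never
    worse than the best lattice point, and the lattice includes the identity,
    so it is never worse than no transformation at all.

    A zero-variance target has no shape to match: the fit degenerates to
    matching the mean level and a warning is emitted.
    """
    if len(g) != len(target) or g.start_day != target.start_day:
        raise ValueError("shape model and target must share the same daily grid")
    w = np.ones(len(g)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != g.values.shape:
        raise ValueError("weights length does not match the curve")
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be nonnegative with a positive sum")
    if np.ptp(target.values) == 0:
        warnings.warn("target curve has zero variance; SMF fit is degenerate",
                      stacklevel=2)

    x = g.days.astype(float)
    tv = target.values

    def objective(params: np.ndarray) -> float:
        sx, sy, t0 = params
        gv = np.interp(sx * (x + t0), x, g.values)
        return _wrmse(sy * (gv + bias) - bias, tv, w)

    # lattice including the identity point
    sxs = np.union1d(np.arange(bounds.sx[0], bounds.sx[1] + 1e-12, grid_steps[0]), [1.0])
    sys_ = np.union1d(np.arange(bounds.sy[0], bounds.sy[1] + 1e-12, grid_steps[1]), [1.0])
    t0s = np.union1d(np.arange(bounds.t0[0], bounds.t0[1] + 1e-12, grid_steps[2]), [0.0])

    SX, SY, T0 = np.meshgrid(sxs, sys_, t0s, indexing="ij")
    args = SX[..., None] * (x[None, None, None, :] + T0[..., None])
    gv = np.interp(args.ravel(), x, g.values).reshape(args.shape)
    h_all = SY[..., None] * (gv + bias) - bias
    obj_all = np.sqrt(np.sum(w * (h_all - tv) ** 2, axis=-1) / w.sum())

    # tie-break toward identity: order candidates by (objective, |sx-1|, |sy-1|, |t0|)
    flat = obj_all.ravel()
    order = np.lexsort((np.abs(T0.ravel()), np.abs(SY.ravel() - 1.0),
                        np.abs(SX.ravel() - 1.0), np.round(flat, 12)))
    best_idx = order[0]
    best = np.array([SX.ravel()[best_idx], SY.ravel()[best_idx], T0.ravel()[best_idx]])
    best_obj = float(flat[best_idx])

    res = minimize(objective, best, method="Nelder-Mead",
                   bounds=[bounds.sx, bounds.sy, bounds.t0],
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    if np.isfinite(res.fun) and res.fun <= best_obj:
        best, best_obj = res.x, float(res.fun)

    sx, sy, t0 = (float(v) for v in best)
    h = smf_transform(g, sx, sy, t0, bias, bounds=None)
    return ShapeModelFit(g=g, sx=sx, sy=sy, t0=t0, bias=bias, h=h, objective=best_obj)
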