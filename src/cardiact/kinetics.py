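"""Patlak graphical analysis on windowed tissue/plasma curve pairs.

The net-influx constant Ki is the slope of the normalized-uptake transform
``Ct(t)/Cp(t)`` against the normalized integrated plasma exposure
``(integral of Cp)/Cp(t)``, fitted by ordinary least squares inside each
analysis window.  MRGlu follows as ``Ki * glucose / LC``.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress

from .errors import InsufficientDataError, InvalidParameterError
from .synthetic_data import Curve

__all__ = [
    "PatlakPoints",
    "PatlakFit",
    "MrgluResult",
    "cumulative_integral",
    "patlak_points",
    "fit_patlak",
    "mrglu",
    "percent_change",
    "volume_reduction",
]


@dataclass(frozen=True)
class PatlakPoints:
    """Patlak-transformed samples: x in minutes, y dimensionless."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    n_dropped: int = 0

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class PatlakFit:
    """Windowed linear fit of the Patlak transform."""

    ki: float  # slope, 1/min
    intercept: float  # apparent distribution volume, dimensionless
    r2: float
    window: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class MrgluResult:
    mrglu: float
    ki: float
    glucose: float
    lc: float


def cumulative_integral(curve: Curve) -> Curve:
    """Cumulative trapezoidal integral of a curve, anchored at zero.

    If the curve starts after t = 0 a zero-valued sample at t = 0 is assumed,
    so the integral measures exposure from the start of the infusion clock.
    """
    t, v = curve.times, curve.values
    if t[0] > 0:
        t = np.concatenate(([0.0], t))
        v = np.concatenate(([0.0], v))
        integ = cumulative_trapezoid(v, t, initial=0.0)[1:]
        t = t[1:]
    else:
        integ = cumulative_trapezoid(v, t, initial=0.0)
    return Curve(t, integ, f"int({curve.label})" if curve.label else "integral")


def patlak_points(
    tissue: Curve, plasma: Curve, eps_rel: float = 1e-9
) -> PatlakPoints:
    """Patlak transform of a tissue/plasma curve pair.

    The plasma curve is linearly resampled onto the tissue grid when the grids
    differ (the tissue frames set the native resolution).  Samples where the
    plasma value is at or below ``eps_rel`` times its maximum are dropped and
    counted in ``n_dropped``.
    """
    t = tissue.times
    if len(plasma) == len(tissue) and np.allclose(plasma.times, t):
        cp = plasma.values.copy()
    else:
        if t[0] < plasma.times[0] or t[-1] > plasma.times[-1]:
            raise InvalidParameterError(
                "tissue time range extends beyond the plasma curve"
            )
        cp = np.asarray(plasma.interp(t), dtype=float)
    int_cp = cumulative_integral(Curve(t, cp)).values
    eps = eps_rel * float(np.max(cp)) if np.max(cp) > 0 else 0.0
    usable = cp > eps
    n_dropped = int((~usable).sum())
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"only {int(usable.sum())} usable Patlak samples (need >= 3)"
        )
    return PatlakPoints(
        x=int_cp[usable] / cp[usable],
        y=tissue.values[usable] / cp[usable],
        t=t[usable],
        n_dropped=n_dropped,
    )


def fit_patlak(points: PatlakPoints, window: tuple[float, float]) -> PatlakFit:
    """Ordinary least-squares line through the Patlak points inside a closed window."""
    a, b = float(window[0]), float(window[1])
    sel = (points.t >= a) & (points.t <= b)
    n = int(sel.sum())
    if n < 3:
        raise InsufficientDataError(
            f"window [{a}, {b}] min contains {n} Patlak points (need >= 3)"
        )
    res = linregress(points.x[sel], points.y[sel])
    return PatlakFit(
        ki=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        window=(a, b),
        n_points=n,
    )


def mrglu(ki: float, glucose: float, lc: float = 1.0) -> MrgluResult:
    """Metabolic rate of glucose: ``Ki * glucose / LC``.

    The lumped constant defaults to 1.0, so MRGlu is reported in
    (glucose units) per minute; relative comparisons are unaffected.
    """
    if lc <= 0:
        raise InvalidParameterError("lumped constant must be positive")
    if glucose < 0:
        raise InvalidParameterError("glucose must be non-negative")
    return MrgluResult(mrglu=ki * glucose / lc, ki=ki, glucose=glucose, lc=lc)


def percent_change(
    before: float, after: float, rounding: str = "truncate"
) -> int | float:
    """Percent decrease from ``before`` to ``after``.

    ``rounding='truncate'`` (default) truncates toward zero to an integer,
    matching how whole-percent drops are conventionally quoted from means;
    ``rounding='none'`` returns the raw float.
    """
    if before <= 0:
        raise InvalidParameterError("before must be positive")
    raw = 100.0 * (before - after) / before
    if rounding == "truncate":
        # round at the 9th decimal first so binary representation noise
        # (e.g. 28.999999999999996 for an exact 29%) cannot shift the floor
        return math.trunc(round(raw, 9))
    if rounding == "none":
        return raw
    raise InvalidParameterError(f"unknown rounding mode {rounding!r}")


def volume_reduction(v_early: float, v_late: float) -> float:
    """Percent reduction of an apparent volume between two timepoints."""
    if v_early <= 0:
        raise InvalidParameterError("v_early must be positive")
    if v_late < 0:
        raise InvalidParameterError("v_late must be non-negative")
    return 100.0 * (v_early - v_late) / v_early
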