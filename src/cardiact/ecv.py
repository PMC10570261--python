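"""Extracellular volume fraction from native and post-contrast T1.

ECV is the ratio of contrast-induced R1 (=1/T1) change in myocardium to that
in blood, scaled by the plasma fraction (1 - hematocrit).  The ratio of R1
differences is invariant to the unit T1 is expressed in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError, InvalidParameterError
from .synthetic_data import T1Table

__all__ = ["EcvInput", "EcvResult", "compute_ecv", "ecv_timeseries"]

DEFAULT_HCT = 0.45  # assumed hematocrit when no measurement is available
DEFAULT_TIMEPOINTS = (40.0, 90.0, 150.0)
NEAREST_SAMPLE_TOL_MIN = 5.0  # half the 10-min T1-map spacing


@dataclass(frozen=True)
class EcvInput:
    """T1 quadruple (ms or any consistent unit) plus hematocrit."""

    native_t1_myo: float
    post_t1_myo: float
    native_t1_blood: float
    post_t1_blood: float
    hct: float = DEFAULT_HCT

    def __post_init__(self) -> None:
        for name in ("native_t1_myo", "post_t1_myo", "native_t1_blood", "post_t1_blood"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not 0.0 < self.hct < 1.0:
            raise InvalidParameterError("hct must be in (0, 1)")


@dataclass(frozen=True)
class EcvResult:
    ecv: float
    timepoint: float | None
    inputs: EcvInput
    out_of_range: bool  # flagged, never clamped


def compute_ecv(inputs: EcvInput, timepoint: float | None = None) -> EcvResult:
    """ECV = (1 - hct) * (R1 change in myocardium) / (R1 change in blood)."""
    d_r1_myo = 1.0 / inputs.post_t1_myo - 1.0 / inputs.native_t1_myo
    d_r1_blood = 1.0 / inputs.post_t1_blood - 1.0 / inputs.native_t1_blood
    if d_r1_blood == 0:
        raise DegenerateInputError(
            "blood R1 change is zero: no contrast arrived in blood"
        )
    ecv = (1.0 - inputs.hct) * d_r1_myo / d_r1_blood
    return EcvResult(
        ecv=float(ecv),
        timepoint=timepoint,
        inputs=inputs,
        out_of_range=not 0.0 <= ecv <= 1.0,
    )


def ecv_timeseries(
    t1_table: T1Table,
    native_t1_myo: float,
    native_t1_blood: float,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    hct: float = DEFAULT_HCT,
    tol: float = NEAREST_SAMPLE_TOL_MIN,
) -> list[EcvResult]:
    """One ECV per requested timepoint, sharing the native T1 pair.

    The nearest table sample strictly within ``tol`` minutes is used for each
    timepoint; a gap of ``tol`` or more raises :class:`InsufficientDataError`
    (at exactly half the map spacing the nearest sample is ambiguous).
    """
    results = []
    for tp in timepoints:
        gaps = np.abs(t1_table.times_min - tp)
        i = int(np.argmin(gaps))
        if gaps[i] >= tol:
            raise InsufficientDataError(
                f"no T1 sample within {tol} min of t = {tp} min "
                f"(nearest at {t1_table.times_min[i]:g} min)"
            )
        inputs = EcvInput(
            native_t1_myo=native_t1_myo,
            post_t1_myo=float(t1_table.t1_myo_ms[i]),
            native_t1_blood=native_t1_blood,
            post_t1_blood=float(t1_table.t1_blood_ms[i]),
            hct=hct,
        )
        results.append(compute_ecv(inputs, timepoint=float(tp)))
    return results
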