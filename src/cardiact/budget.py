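"""Tissue-fraction ledger bounding the viable-myocyte volume in infarcted tissue.

Unit tissue volume is partitioned into extracellular volume, fibrosis,
fibroblasts, and whatever remains for myocytes; the remainder is an upper
bound on the viable-myocyte fraction because other cell types (inflammatory,
dead cells) are not subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InfeasibleBudgetError, InvalidParameterError

__all__ = [
    "VolumeBudget",
    "viable_myocyte_bound",
    "fraction_of_baseline",
    "required_viable_fraction",
    "BASELINE_MYOCYTE_FRACTION",
]

BASELINE_MYOCYTE_FRACTION = 0.75  # myocyte share of normal myocardial volume


def _check_fraction(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise InvalidParameterError(f"{name} must be a fraction in [0, 1]")
    return float(value)


@dataclass(frozen=True)
class VolumeBudget:
    """Volumetric ledger; components plus ``myocyte_bound`` sum to one."""

    ecv: float
    fibrosis: float
    fibroblast: float
    baseline_myocyte: float = BASELINE_MYOCYTE_FRACTION

    def __post_init__(self) -> None:
        _check_fraction("ecv", self.ecv)
        _check_fraction("fibrosis", self.fibrosis)
        _check_fraction("fibroblast", self.fibroblast)
        _check_fraction("baseline_myocyte", self.baseline_myocyte)
        if self.ecv + self.fibrosis + self.fibroblast > 1.0:
            raise InfeasibleBudgetError("tissue fractions exceed unit volume")

    @property
    def myocyte_bound(self) -> float:
        return 1.0 - self.ecv - self.fibrosis - self.fibroblast

    @property
    def bound_vs_baseline(self) -> float:
        return fraction_of_baseline(self.myocyte_bound, self.baseline_myocyte)

    def as_dict(self) -> dict[str, float]:
        return {
            "ecv": self.ecv,
            "fibrosis": self.fibrosis,
            "fibroblast": self.fibroblast,
            "myocyte_bound": self.myocyte_bound,
            "baseline_myocyte": self.baseline_myocyte,
            "bound_vs_baseline": self.bound_vs_baseline,
        }


def viable_myocyte_bound(ecv: float, fibrosis: float, fibroblast: float) -> float:
    """Maximum viable-myocyte fraction: 1 - ecv - fibrosis - fibroblast."""
    return VolumeBudget(ecv=ecv, fibrosis=fibrosis, fibroblast=fibroblast).myocyte_bound


def fraction_of_baseline(numerator: float, baseline: float = BASELINE_MYOCYTE_FRACTION) -> float:
    """A tissue fraction expressed relative to the baseline myocyte fraction."""
    if baseline <= 0:
        raise InvalidParameterError("baseline must be positive")
    return numerator / baseline


def required_viable_fraction(
    infarct_before: float,
    infarct_after: float,
    remote_before: float,
    remote_after: float,
) -> float:
    """Viable fraction needed for myocytes alone to explain the infarct's drop.

    Implemented as the ratio of fractional decreases,
    ``(infarct drop / infarct baseline) / (remote drop / remote baseline)``.
    This is an interpretation: it assumes infarct myocytes suppress like remote
    ones, so the infarct's shallower relative drop scales to the fraction of
    still-viable myocytes.  Flag it as such in any report.
    """
    if infarct_before <= 0 or remote_before <= 0:
        raise InvalidParameterError("baseline values must be positive")
    remote_drop = (remote_before - remote_after) / remote_before
    if remote_drop <= 0:
        raise InvalidParameterError(
            "remote decrease must be positive for the ratio to be defined"
        )
    infarct_drop = (infarct_before - infarct_after) / infarct_before
    return infarct_drop / remote_drop
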