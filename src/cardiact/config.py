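"""Run configuration: a validated, strictly-typed schema for the pipeline.

Unknown keys are rejected everywhere so a typo in a config file fails loudly
instead of silently falling back to a default.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import FormatError
from .synthetic_data import FdgKinetics, GdKinetics, InfusionProtocol

__all__ = ["RunConfig", "load_config", "default_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    t_start: float = 0.0
    t_end: float = 150.0
    gd_rate: float = 4.0
    fdg_rate: float = 25.0 / 150.0
    suppression_onset: float = 40.0
    lipid_duration: float = 50.0
    windows: list[tuple[float, float]] = Field(
        default=[(10.0, 40.0), (60.0, 90.0), (120.0, 150.0)]
    )

    def build(self) -> InfusionProtocol:
        return InfusionProtocol(
            t_start=self.t_start,
            t_end=self.t_end,
            gd_rate=self.gd_rate,
            fdg_rate=self.fdg_rate,
            suppression_onset=self.suppression_onset,
            lipid_duration=self.lipid_duration,
            windows=tuple(self.windows),
        )


class FdgRegionConfig(_Strict):
    k1: float = 0.1
    k2: float = 0.6
    k3: float = 0.15
    vb: float = 0.05
    suppression_factor: float = 0.1
    transition_tau: float = 5.0

    def build(self) -> FdgKinetics:
        return FdgKinetics(
            k1=self.k1,
            k2=self.k2,
            k3=self.k3,
            vb=self.vb,
            suppression_factor=self.suppression_factor,
            transition_tau=self.transition_tau,
        )


class FdgConfig(_Strict):
    plasma_vd: float = 150.0  # mL/kg
    plasma_kel: float = 0.1  # 1/min
    frame_len: float = 3.0  # min, PET framing
    noise_cv: float = 0.0  # multiplicative TAC noise
    regions: dict[str, FdgRegionConfig] = Field(
        default_factory=lambda: {
            # remote myocardium suppresses strongly; infarct retains uptake
            # (inflammatory cells keep trapping)
            "remote": FdgRegionConfig(suppression_factor=0.1),
            "infarct": FdgRegionConfig(suppression_factor=0.55),
        }
    )


class GdRegionConfig(_Strict):
    ktrans: float = 0.25
    ve: float = 0.2
    vp: float = 0.0

    def build(self, base: "GdConfig") -> GdKinetics:
        return GdKinetics(
            ktrans=self.ktrans,
            ve=self.ve,
            vp=self.vp,
            r1=base.r1,
            t10_tissue=base.t10_tissue,
            t10_blood=base.t10_blood,
            hct=base.hct,
        )


class GdConfig(_Strict):
    plasma_vd: float = 250.0  # mL/kg -> concentrations in mM at 4 umol/min/kg
    plasma_kel: float = 0.05  # 1/min
    r1: float = 4.5  # 1/(mM*s)
    t10_tissue: float = 1100.0  # ms
    t10_blood: float = 1600.0  # ms
    hct: float = 0.45
    t1_sample_every: float = 10.0  # min
    t1_noise_sd: float = 0.0  # ms
    regions: dict[str, GdRegionConfig] = Field(
        default_factory=lambda: {
            "remote": GdRegionConfig(ve=0.2),
            "infarct": GdRegionConfig(ve=0.48),
        }
    )


class HistologyConfig(_Strict):
    enabled: bool = True
    slide_shape: tuple[int, int] = (96, 96)
    blob_scale: float = 6.0
    blue_margin: float = 20.0
    luminance_floor: float = 30.0
    # per-region ground-truth fibrosis fractions, one slide per entry
    truth_fractions: dict[str, list[float]] = Field(
        default_factory=lambda: {
            "center": [0.28, 0.33, 0.30],
            "edge": [0.14, 0.18, 0.16],
            "remote": [0.010, 0.015, 0.012],
            "right_ventricle": [0.012, 0.018, 0.015],
        }
    )
    puncta_per_region: dict[str, int] = Field(
        default_factory=lambda: {"center": 60, "edge": 30, "remote": 5}
    )


class StatsConfig(_Strict):
    cohort_n: int = 7
    jitter_cv: float = 0.15  # subject-level multiplicative spread


class BudgetConfig(_Strict):
    fibrosis: float = 0.04
    fibroblast: float = 0.04
    baseline_myocyte: float = 0.75
    ecv_region: str = "infarct"  # pipeline takes ECV at the last timepoint here


class RunConfig(_Strict):
    seed: int
    grid: float = 0.1  # simulation step, min
    glucose: float = 5.5  # blood glucose at infusion start
    lc: float = 1.0  # lumped constant
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    fdg: FdgConfig = Field(default_factory=FdgConfig)
    gd: GdConfig = Field(default_factory=GdConfig)
    histology: HistologyConfig = Field(default_factory=HistologyConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    budget: BudgetConfig = Field(default_factory=BudgetConfig)


def default_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed)


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except FileNotFoundError:
        raise FormatError(f"{path}: file not found") from None
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from None
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise FormatError(f"{path}: invalid config: {exc}") from None
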