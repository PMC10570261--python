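"""File formats: curve/T1 CSV, results JSON, and slide TIFF + truth sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .stats import _canonical
from .synthetic_data import Curve, SyntheticSlide, T1Table

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "read_t1_csv",
    "write_t1_csv",
    "write_results_json",
    "read_results_json",
    "write_slide",
    "read_image",
]

CURVE_COLUMNS = ["time_min", "value", "label"]
T1_COLUMNS = ["time_min", "t1_myo_ms", "t1_blood_ms"]


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    return df


def _check_increasing(path, times: np.ndarray) -> None:
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        # +3: header line, 1-based, and the offence is at the *second* of the pair
        raise FormatError(
            f"{path}: times not strictly increasing at line {int(bad[0]) + 3}"
        )


def read_curve_csv(path) -> Curve:
    """Read a curve CSV with header ``time_min,value,label``."""
    df = _read_csv(path, CURVE_COLUMNS[:2])
    times = df["time_min"].to_numpy(dtype=float)
    _check_increasing(path, times)
    label = ""
    if "label" in df.columns and len(df):
        label = str(df["label"].iloc[0])
    return Curve(times, df["value"].to_numpy(dtype=float), label)


def write_curve_csv(curve: Curve, path) -> None:
    df = pd.DataFrame(
        {
            "time_min": curve.times,
            "value": curve.values,
            "label": curve.label,
        }
    )
    df.to_csv(path, index=False)


def read_t1_csv(path) -> T1Table:
    """Read a T1 table CSV with header ``time_min,t1_myo_ms,t1_blood_ms``."""
    df = _read_csv(path, T1_COLUMNS)
    times = df["time_min"].to_numpy(dtype=float)
    _check_increasing(path, times)
    return T1Table(
        times,
        df["t1_myo_ms"].to_numpy(dtype=float),
        df["t1_blood_ms"].to_numpy(dtype=float),
    )


def write_t1_csv(table: T1Table, path) -> None:
    pd.DataFrame(
        {
            "time_min": table.times_min,
            "t1_myo_ms": table.t1_myo_ms,
            "t1_blood_ms": table.t1_blood_ms,
        }
    ).to_csv(path, index=False)


def write_results_json(results: dict, path) -> None:
    """Write a results document: version-stamped, keys sorted, floats at 12 s.f."""
    if not isinstance(results, dict):
        raise FormatError("results document must be a JSON object")
    from . import __version__

    doc = dict(results)
    doc.setdefault("cardiact_version", __version__)
    Path(path).write_text(
        json.dumps(_canonical(doc), sort_keys=True, indent=2) + "\n"
    )


def read_results_json(path) -> dict:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from None
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: results document must be a JSON object")
    if "cardiact_version" not in doc:
        raise FormatError(f"{path}: missing version stamp")
    return doc


def write_slide(slide: SyntheticSlide, path) -> None:
    """Write a slide as TIFF plus a ``.truth.json`` sidecar with its ground truth."""
    import tifffile

    path = Path(path)
    pixels = slide.pixels
    if pixels.dtype not in (np.uint8, np.uint16):
        # float rasters are scaled into uint16 for storage
        vmax = float(pixels.max()) or 1.0
        pixels = np.round(pixels / vmax * 65535).astype(np.uint16)
    tifffile.imwrite(path, pixels)
    truth: dict = {}
    if slide.truth_fraction is not None:
        truth["truth_fraction"] = slide.truth_fraction
    if slide.truth_spots is not None:
        truth["truth_spots"] = [list(s) for s in slide.truth_spots]
    if slide.region is not None:
        truth["region"] = slide.region
    write_results_json(truth, path.parent / (path.name + ".truth.json"))


def read_image(path) -> np.ndarray:
    """Read a TIFF/PNG raster (RGB uint8 or grayscale 8/16-bit)."""
    import imageio.v3 as iio

    try:
        return np.asarray(iio.imread(path))
    except Exception as exc:
        raise FormatError(f"{path}: cannot read image ({exc})") from None
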