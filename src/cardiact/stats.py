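"""Statistical comparisons and deterministic report assembly.

Paired two-tailed t-tests across suppression states, Bonferroni adjustment,
an exact/asymptotic Mann-Whitney U test for region comparisons, Pearson
correlation, and a Shapiro-Wilk normality gate routing non-normal data to the
nonparametric test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "TestResult",
    "CorrelationResult",
    "NormalityResult",
    "paired_ttest",
    "bonferroni",
    "mann_whitney",
    "pearson",
    "normality_gate",
    "build_report",
    "EXACT_MW_MAX_N",
]

EXACT_MW_MAX_N = 8  # exact Mann-Whitney below/at this min sample size
ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n: tuple[int, ...]
    adjusted_p: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class NormalityResult:
    passed: bool
    p_value: float
    n: int
    flag: str | None = None


def paired_ttest(x, y) -> TestResult:
    """Two-tailed paired t-test.

    Identical pairs (all differences exactly zero) are reported as the null
    result t = 0, p = 1 rather than an error; a *constant nonzero* difference
    has no sampling variance and is degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("paired samples must be equal-length 1-D")
    n = x.size
    if n < 2:
        raise InvalidParameterError("need at least two pairs")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult(0.0, 1.0, "paired_ttest", (n,))
        raise DegenerateInputError("differences have zero variance")
    res = sps.ttest_rel(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), "paired_ttest", (n,))


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: ``min(1, p * m)`` for each p-value."""
    p = [float(v) for v in p_values]
    if m is None:
        m = len(p)
    if m < 1:
        raise InvalidParameterError("number of comparisons must be >= 1")
    if m < len(p):
        raise InvalidParameterError("m must be at least the number of p-values")
    if any(not 0.0 <= v <= 1.0 for v in p):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return [min(1.0, v * m) for v in p]


def mann_whitney(x, y) -> TestResult:
    """Two-tailed Mann-Whitney U test (unpaired).

    Uses the exact null distribution when ``min(n1, n2) <= 8``, otherwise the
    normal approximation with tie correction and continuity correction.  The
    reported statistic is the U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    exact = min(x.size, y.size) <= EXACT_MW_MAX_N
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        f"mann_whitney_{method}",
        (int(x.size), int(y.size)),
    )


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with two-tailed p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("samples must be equal-length 1-D")
    if x.size < 3:
        raise InvalidParameterError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in one of the samples")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def normality_gate(x, alpha: float = ALPHA) -> NormalityResult:
    """Shapiro-Wilk gate: fail routes the downstream comparison to Mann-Whitney."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InvalidParameterError("need at least three observations")
    if np.ptp(x) == 0:
        return NormalityResult(False, 0.0, int(x.size), flag="constant_sample")
    res = sps.shapiro(x)
    p = float(res.pvalue)
    return NormalityResult(p >= alpha, p, int(x.size))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def _round_sig(value: float, sig: int = 12) -> float:
    if value == 0 or not np.isfinite(value):
        return float(value)
    return float(f"{value:.{sig}g}")


def _canonical(obj):
    """Recursively sort keys and normalize floats for byte-stable JSON."""
    if isinstance(obj, dict):
        return {str(k): _canonical(obj[k]) for k in sorted(obj, key=str)}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (float, np.floating)):
        return _round_sig(float(obj))
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_canonical(v) for v in obj.tolist()]
    return obj


def build_report(sections: dict, seed: int | None = None, config: dict | None = None) -> tuple[str, str]:
    """Assemble the run report as (canonical JSON string, Markdown summary).

    The JSON is deterministic: keys sorted, floats normalized to 12
    significant digits, no timestamps.  Empty optional sections are omitted.
    """
    if not sections or all(v in (None, {}, []) for v in sections.values()):
        raise InvalidParameterError("report needs at least one non-empty section")
    from . import __version__

    doc: dict = {"cardiact_version": __version__}
    if seed is not None:
        doc["seed"] = int(seed)
    if config is not None:
        doc["config"] = config
    for name, content in sections.items():
        if content in (None, {}, []):
            continue
        doc[name] = content
    doc = _canonical(doc)
    json_str = json.dumps(doc, sort_keys=True, indent=2) + "\n"

    lines = ["# cardiact run report", ""]
    if seed is not None:
        lines.append(f"- seed: {seed}")
    lines.append(f"- version: {__version__}")
    lines.append("")
    for name in sorted(k for k in doc if k not in ("cardiact_version", "seed", "config")):
        lines.append(f"## {name}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(doc[name], sort_keys=True, indent=2))
        lines.append("```")
        lines.append("")
    return json_str, "\n".join(lines)
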