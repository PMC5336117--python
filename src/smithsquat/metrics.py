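"""Validation measures for motion and muscle-activity comparison.

NRMSE (RMSE divided by the reference range, in percent), Pearson correlation
with its two-sided p-value, cycle-fraction peak timing, the thresholded
total-muscle-activity summary, and the exact table-aggregation arithmetic
used for summary averages of published per-case validation tables (shipped
with the package under ``data/reference_tables``).

Table averages are computed in exact decimal arithmetic and displayed with
round-half-even at the table's precision, which is the convention that
reproduces the published summary rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonReport",
    "nrmse",
    "pearson",
    "peak_timing",
    "total_muscle_activity",
    "aggregate_mean",
    "round_display",
    "load_reference_table",
    "compare_series",
]


class DegenerateRangeError(ValueError):
    """Reference series has zero range; NRMSE undefined."""


class UndefinedCorrelationError(ValueError):
    """A constant series has no defined Pearson correlation."""


def nrmse(reference, test) -> float:
    """100 x RMSE(reference, test) / (max(reference) - min(reference))."""
    ref = np.asarray(reference, float)
    tst = np.asarray(test, float)
    if ref.shape != tst.shape or ref.size < 2:
        raise ValueError("series must share a length of at least 2")
    rng = float(ref.max() - ref.min())
    if rng <= 0.0:
        raise DegenerateRangeError("reference range is zero")
    rmse = float(np.sqrt(np.mean((ref - tst) ** 2)))
    return 100.0 * rmse / rng


def pearson(a, b):
    """Product-moment correlation with the two-sided t-transform p-value."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must share a length of at least 3")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise UndefinedCorrelationError("constant series")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def peak_timing(series) -> float:
    """Cycle fraction of the global maximum (earliest frame on ties)."""
    s = np.asarray(series, float)
    if s.size == 0:
        raise ValueError("empty series")
    if s.size == 1:
        return 0.0
    return float(np.argmax(s)) / (s.size - 1)


def total_muscle_activity(series, threshold: float = 0.20) -> float:
    """Cycle summary of an activity series, in percent.

    Mean over the full cycle of the samples at or above ``threshold``
    (sub-threshold samples contribute zero), times 100.
    """
    s = np.asarray(series, float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("activity values must lie in [0, 1]")
    kept = np.where(s >= threshold, s, 0.0)
    return 100.0 * float(np.mean(kept))


def round_display(value, ndigits: int) -> float:
    """Round-half-even at ``ndigits`` decimals using exact decimal arithmetic.

    Accepts floats, strings or Decimals; strings/Decimals preserve the exact
    printed value (use them for table cells).
    """
    d = value if isinstance(value, Decimal) else Decimal(str(value))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_EVEN))


def aggregate_mean(cells, ndigits: int | None = None) -> float:
    """Arithmetic mean of a table selection, optionally display-rounded.

    ``cells`` is any iterable of numbers (or numeric strings, which keep
    exact decimal values).  The mean is computed exactly in decimal
    arithmetic; ``ndigits`` applies round-half-even display rounding.
    """
    vals = [c if isinstance(c, Decimal) else Decimal(str(c)) for c in cells]
    if not vals:
        raise ValueError("empty selection")
    mean = sum(vals) / Decimal(len(vals))
    if ndigits is None:
        return float(mean)
    return round_display(mean, ndigits)


REFERENCE_TABLES = (
    "activity_nrmse", "activity_pearson", "activity_peak_timing",
    "activity_total", "angle_nrmse", "angle_pearson",
    "moment_nrmse", "moment_pearson",
)


def load_reference_table(name: str) -> pd.DataFrame:
    """A published per-case validation table as strings (exact cells).

    Index columns ``foot_ratio`` and ``guide_deg`` identify the case; the
    remaining columns are metric cells kept as strings so that decimal
    aggregation is exact.
    """
    if name not in REFERENCE_TABLES:
        raise KeyError(f"unknown reference table {name!r}; "
                       f"available: {REFERENCE_TABLES}")
    path = resources.files("smithsquat").joinpath(
        "data", "reference_tables", f"{name}.csv")
    with path.open("r") as fh:
        return pd.read_csv(fh, dtype=str)


@dataclass(frozen=True)
class ComparisonReport:
    """Agreement summary between a reference and a test series."""

    nrmse_pct: float
    pearson_r: float
    pearson_p: float
    peak_timing_ref: float
    peak_timing_test: float
    n_samples: int


def compare_series(reference, test) -> ComparisonReport:
    r, p = pearson(reference, test)
    return ComparisonReport(
        nrmse_pct=nrmse(reference, test),
        pearson_r=r, pearson_p=p,
        peak_timing_ref=peak_timing(reference),
        peak_timing_test=peak_timing(test),
        n_samples=int(np.asarray(reference).size),
    )
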