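"""Counting-accuracy statistics: RMSE, relative RMSE, R², error histogram.

For n images with manual counts t_i and automatic counts d_i:

    RMSE  = sqrt( (1/n) Σ (t_i − d_i)² )                 [spikelets]
    rRMSE = sqrt( (1/n) Σ ((t_i − d_i)/t_i)² )           [fraction; ×100 = %]
    R²    = 1 − Σ(t_i − d_i)² / Σ(t_i − t̄)²

R² uses the total sum of squares of the *manual* counts, so a predictor
worse than the manual mean gives a negative value — that is intentional and
kept.  The error distribution is the histogram of signed errors d_i − t_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountComparison",
    "CountReport",
    "rmse",
    "rrmse",
    "r_squared",
    "error_distribution",
    "count_report",
    "plot_count_scatter",
]


@dataclass
class CountComparison:
    """Paired per-image manual (t) and automatic (d) spikelet counts."""

    manual: np.ndarray
    automatic: np.ndarray
    image_ids: list[str] = field(default_factory=list)
    wheat_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.manual = np.asarray(self.manual, dtype=np.int64)
        self.automatic = np.asarray(self.automatic, dtype=np.int64)
        if self.manual.shape != self.automatic.shape or self.manual.ndim != 1:
            raise ValueError("manual and automatic must be equal-length 1-d vectors")
        if np.any(self.manual < 0) or np.any(self.automatic < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.manual.size)


def rmse(c: CountComparison) -> float:
    """Root mean squared counting error, in spikelets."""
    if c.n == 0:
        raise ValueError("empty comparison")
    return float(np.sqrt(np.mean((c.manual - c.automatic) ** 2)))


def rrmse(c: CountComparison) -> float:
    """Relative RMSE as a fraction (multiply by 100 to report %)."""
    if c.n == 0:
        raise ValueError("empty comparison")
    if np.any(c.manual == 0):
        raise ValueError("rRMSE undefined: some manual count is zero")
    rel = (c.manual - c.automatic) / c.manual
    return float(np.sqrt(np.mean(rel**2)))


def r_squared(c: CountComparison) -> float:
    """Coefficient of determination of automatic against manual counts.

    Can be negative when the automatic counts predict worse than the mean
    manual count.
    """
    if c.n < 2:
        raise ValueError("R² needs at least 2 images")
    ss_tot = float(np.sum((c.manual - c.manual.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² undefined: manual counts are constant")
    ss_res = float(np.sum((c.manual - c.automatic) ** 2))
    return 1.0 - ss_res / ss_tot


def error_distribution(c: CountComparison) -> dict[int, int]:
    """Histogram of signed counting errors d_i − t_i."""
    if c.n == 0:
        raise ValueError("empty comparison")
    errs = c.automatic - c.manual
    vals, freqs = np.unique(errs, return_counts=True)
    return {int(v): int(f) for v, f in zip(vals, freqs)}


@dataclass
class CountReport:
    """All counting metrics for one group of images."""

    n: int
    rmse: float
    rrmse: float  # fraction
    r2: float
    error_histogram: dict[int, int]
    within_one_fraction: float  # share of images with |d − t| <= 1


def count_report(c: CountComparison) -> CountReport:
    hist = error_distribution(c)
    within = sum(f for e, f in hist.items() if abs(e) <= 1) / c.n
    return CountReport(
        n=c.n,
        rmse=rmse(c),
        rrmse=rrmse(c),
        r2=r_squared(c),
        error_histogram=hist,
        within_one_fraction=within,
    )


def report_by_line(c: CountComparison) -> dict[str, CountReport]:
    """Per-wheat-line reports plus a pooled one under key ``'all'``."""
    out: dict[str, CountReport] = {}
    if c.wheat_lines:
        for line in sorted(set(c.wheat_lines)):
            idx = [i for i, l in enumerate(c.wheat_lines) if l == line]
            out[line] = count_report(
                CountComparison(c.manual[idx], c.automatic[idx])
            )
    out["all"] = count_report(c)
    return out


def comparison_from_frame(df: pd.DataFrame) -> CountComparison:
    """Build a comparison from a table with columns
    image_id, manual_count, automatic_count[, wheat_line]."""
    lines = list(df["wheat_line"]) if "wheat_line" in df else []
    return CountComparison(
        manual=df["manual_count"].to_numpy(),
        automatic=df["automatic_count"].to_numpy(),
        image_ids=list(df["image_id"]) if "image_id" in df else [],
        wheat_lines=lines,
    )


def plot_count_scatter(c: CountComparison, ax=None):
    """Manual-vs-automatic scatter with the least-squares line (automatic
    regressed on manual) and the 1:1 line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t, d = c.manual, c.automatic
    ax.scatter(t, d, s=12, alpha=0.7)
    slope, intercept = np.polyfit(t, d, 1)
    xs = np.array([t.min(), t.max()], dtype=float)
    ax.plot(xs, slope * xs + intercept, "r-", label="least squares (d on t)")
    lo, hi = min(t.min(), d.min()), max(t.max(), d.max())
    ax.plot([lo, hi], [lo, hi], "k--", label="1:1")
    ax.set_xlabel("manual count")
    ax.set_ylabel("automatic count")
    ax.legend()
    return ax
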