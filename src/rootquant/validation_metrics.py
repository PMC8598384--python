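"""Accuracy statistics for estimated-vs-ground-truth trait comparisons.

Mean bias error reports the direction and magnitude of systematic error,
root-mean-square error the spread of the residuals, and the determination
coefficient the squared Pearson correlation between estimates and truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["PairedSeries", "mbe", "rmse", "r_squared", "benchmark_report"]


@dataclass
class PairedSeries:
    """Estimated values P_i paired with observed ground truth O_i."""

    estimated: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.estimated = np.asarray(self.estimated, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.estimated.shape != self.observed.shape or self.estimated.ndim != 1:
            raise ValueError("estimated and observed must be 1-D of equal length")

    @property
    def n(self) -> int:
        return len(self.estimated)


def mbe(s: PairedSeries) -> float:
    """Mean bias error (1/N) * sum(P_i - O_i); positive = overestimation."""
    if s.n == 0:
        raise ValueError("MBE requires at least one pair")
    return float(np.mean(s.estimated - s.observed))


def rmse(s: PairedSeries) -> float:
    """Root mean square error sqrt(sum((P_i - O_i)^2) / N)."""
    if s.n == 0:
        raise ValueError("RMSE requires at least one pair")
    return float(np.sqrt(np.mean((s.estimated - s.observed) ** 2)))


def r_squared(s: PairedSeries) -> float:
    """Squared Pearson correlation between estimated and observed values."""
    if s.n < 2:
        raise ValueError("R^2 requires at least two pairs")
    x, y = s.observed, s.estimated
    n = s.n
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = (n * np.sum(x * x) - np.sum(x) ** 2) * (n * np.sum(y * y) - np.sum(y) ** 2)
    if den <= 0:
        raise ValueError("R^2 undefined for a constant series")
    return float(num ** 2 / den)


def benchmark_report(pairs: dict) -> pd.DataFrame:
    """Metrics table (trait, RMSE, MBE, R^2, n) from a mapping of trait name
    to PairedSeries."""
    rows = []
    for trait, series in pairs.items():
        try:
            r2 = r_squared(series)
        except ValueError:  # short or constant series: R^2 undefined
            r2 = float("nan")
        rows.append({
            "trait": trait,
            "RMSE": rmse(series),
            "MBE": mbe(series),
            "R2": r2,
            "n": series.n,
        })
    return pd.DataFrame(rows, columns=["trait", "RMSE", "MBE", "R2", "n"])
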