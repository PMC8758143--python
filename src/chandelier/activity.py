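"""Correlation analysis of calcium activity and behavioral covariates.

Cell traces are downsampled (Fourier resampling, e.g. 30 Hz -> 12 Hz),
pairwise cell-cell Pearson correlations are computed over spontaneous
periods, per-cell correlations against pupil area and locomotion speed are
reported, and group comparisons use the Mann-Whitney U test (unpaired) or
the Wilcoxon signed-rank test (paired, matched cell-behavior pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "TraceBundle",
    "resample_trace",
    "pairwise_correlations",
    "behavior_correlations",
    "group_difference_tests",
]


@dataclass
class TraceBundle:
    """Cell traces with behavior covariates on a common time base."""

    traces: np.ndarray  # (n_cells, n_samples)
    rate: float  # Hz
    pupil: np.ndarray | None = None
    locomotion: np.ndarray | None = None
    mask: np.ndarray | None = None  # spontaneous-period mask

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, float))
        n = self.traces.shape[1]
        if self.mask is None:
            self.mask = np.ones(n, bool)
        self.mask = np.asarray(self.mask, bool)
        if len(self.mask) != n:
            raise ValueError("mask length must equal sample count")
        for name in ("pupil", "locomotion"):
            v = getattr(self, name)
            if v is not None and len(np.asarray(v)) != n:
                raise ValueError(f"{name} length must equal sample count")


def resample_trace(trace, from_hz: float, to_hz: float) -> np.ndarray:
    """Fourier-method resampling to round(n * to/from) samples."""
    if from_hz <= 0 or to_hz <= 0:
        raise ValueError("rates must be positive")
    trace = np.asarray(trace, float)
    n_out = int(round(len(trace) * to_hz / from_hz))
    if n_out < 2:
        raise ValueError("resampled trace would have fewer than 2 samples")
    if n_out == len(trace):
        return trace.copy()
    return signal.resample(trace, n_out)


def pairwise_correlations(traces, mask=None) -> pd.DataFrame:
    """Pearson r for every unordered cell pair over masked samples.

    Zero-variance traces are flagged and their pairs excluded (r = NaN);
    the returned frame has columns cell_a, cell_b, r, excluded.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    n_cells, n = traces.shape
    if n_cells < 2:
        raise ValueError("need at least two cells")
    if mask is None:
        mask = np.ones(n, bool)
    mask = np.asarray(mask, bool)
    if mask.sum() < 3:
        raise ValueError("masked length must be >= 3")
    X = traces[:, mask]
    sd = X.std(axis=1)
    rows = []
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            if sd[i] == 0 or sd[j] == 0:
                rows.append({"cell_a": i, "cell_b": j, "r": np.nan,
                             "excluded": True})
            else:
                r = float(np.corrcoef(X[i], X[j])[0, 1])
                rows.append({"cell_a": i, "cell_b": j, "r": r,
                             "excluded": False})
    return pd.DataFrame(rows)


def behavior_correlations(traces, behavior: dict, mask=None) -> pd.DataFrame:
    """Per-cell Pearson r against each behavioral trace.

    ``behavior`` maps a name (e.g. "pupil", "locomotion") to a trace.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    n_cells, n = traces.shape
    if mask is None:
        mask = np.ones(n, bool)
    mask = np.asarray(mask, bool)
    if mask.sum() < 3:
        raise ValueError("masked length must be >= 3")
    rows = []
    for name, b in behavior.items():
        b = np.asarray(b, float)[mask]
        if b.std() == 0:
            raise ValueError(f"behavior trace {name!r} has zero variance")
        for i in range(n_cells):
            x = traces[i, mask]
            if x.std() == 0:
                rows.append({"cell": i, "behavior": name, "r": np.nan,
                             "excluded": True})
            else:
                rows.append({"cell": i, "behavior": name,
                             "r": float(np.corrcoef(x, b)[0, 1]),
                             "excluded": False})
    return pd.DataFrame(rows)


def group_difference_tests(group_a, group_b, paired: bool = False) -> dict:
    """Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired), two-sided."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired groups must have equal length")
        diff = a - b
        if np.all(diff == 0):
            return {"test": "wilcoxon", "statistic": 0.0, "p": 1.0,
                    "degenerate": True}
        stat, p = stats.wilcoxon(a, b)
        return {"test": "wilcoxon", "statistic": float(stat), "p": float(p),
                "degenerate": False}
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"test": "mannwhitneyu", "statistic": float(stat), "p": float(p),
            "degenerate": False}
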