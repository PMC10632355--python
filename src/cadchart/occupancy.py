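"""Open/closed chromatin calling by empirical FDR against background regions.

A single global RPKM threshold is calibrated by comparing the pooled peak
signal distribution with the pooled signal over shuffled, length-matched
background regions: at a candidate threshold t the empirical false discovery
rate is the number of background values at or above t divided by the number
of peak values at or above t. The smallest threshold meeting the target FDR
is applied to stage-level signal to produce a binary open/closed state
matrix (value >= threshold means open).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class UncalibratableError(RuntimeError):
    """No grid threshold achieves the target FDR."""

    def __init__(self, target: float, achieved: float):
        self.target = target
        self.achieved = achieved
        super().__init__(
            f"no threshold reaches target FDR {target}; minimum achieved {achieved:.4g}"
        )


@dataclass
class FdrCurve:
    """Empirical FDR as a function of the RPKM threshold.

    ``fdr_values`` is the raw estimator |background >= t| / max(|peaks >= t|, 1);
    ``fdr_monotone`` is its non-increasing envelope (running minimum along the
    ascending grid), the form used for diagnostics and plotting. Both select
    the same calibrated threshold.
    """

    thresholds: np.ndarray
    fdr_values: np.ndarray
    fdr_monotone: np.ndarray
    n_peak_values: np.ndarray
    n_background_values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "fdr": self.fdr_values,
                "fdr_monotone": self.fdr_monotone,
                "n_peaks_ge": self.n_peak_values,
                "n_background_ge": self.n_background_values,
            }
        )


@dataclass
class StateMatrix:
    """Binary open(1)/closed(0) chromatin states, peaks x ordered stages."""

    states: pd.DataFrame
    threshold_used: float

    def __post_init__(self):
        if self.threshold_used <= 0:
            raise ValueError("threshold_used must be positive")
        vals = self.states.to_numpy()
        if len(vals) and not np.isin(vals, (0, 1)).all():
            raise ValueError("states must be binary")

    @property
    def peak_ids(self) -> pd.Index:
        return self.states.index

    @property
    def stage_labels(self) -> list[str]:
        return list(self.states.columns)


def _pool(values) -> np.ndarray:
    if isinstance(values, pd.DataFrame):
        arr = values.to_numpy(dtype=float).ravel()
    else:
        arr = np.asarray(values, dtype=float).ravel()
    return arr


def fdr_curve(peak_values, background_values, grid: Sequence[float]) -> FdrCurve:
    """Empirical FDR over a threshold grid.

    At each threshold t, FDR(t) = |{background >= t}| / max(|{peaks >= t}|, 1).
    """
    peaks = np.sort(_pool(peak_values))
    background = np.sort(_pool(background_values))
    if peaks.size == 0 or background.size == 0:
        raise ValueError("peak and background value sets must be nonempty")
    grid = np.asarray(grid, dtype=float)
    n_peak = peaks.size - np.searchsorted(peaks, grid, side="left")
    n_bg = background.size - np.searchsorted(background, grid, side="left")
    raw = n_bg / np.maximum(n_peak, 1)
    raw = np.clip(raw, 0.0, 1.0)
    return FdrCurve(
        thresholds=grid,
        fdr_values=raw,
        fdr_monotone=np.minimum.accumulate(raw),
        n_peak_values=n_peak,
        n_background_values=n_bg,
    )


def default_grid(peak_values, grid_step: float = 0.01) -> np.ndarray:
    """Thresholds from 0 to the 99.9th percentile of pooled peak values."""
    pool = _pool(peak_values)
    top = float(np.percentile(pool, 99.9)) if pool.size else grid_step
    return np.arange(0.0, top + grid_step, grid_step)


def calibrate_threshold(
    peak_matrix,
    background_matrix,
    target_fdr: float = 0.01,
    grid_step: float = 0.01,
    grid: Sequence[float] | None = None,
) -> tuple[float, FdrCurve]:
    """Smallest grid threshold whose empirical FDR meets the target.

    Values are pooled across all samples so one global threshold applies to
    every sample. Raises :class:`UncalibratableError` when no grid point
    reaches the target, reporting the minimum FDR achieved.
    """
    if not 0 < target_fdr < 1:
        raise ValueError("target_fdr must be in (0, 1)")
    if grid is None:
        grid = default_grid(peak_matrix, grid_step)
    curve = fdr_curve(peak_matrix, background_matrix, grid)
    ok = np.flatnonzero(curve.fdr_values <= target_fdr)
    if ok.size == 0:
        raise UncalibratableError(target_fdr, float(curve.fdr_values.min()))
    threshold = float(curve.thresholds[ok[0]])
    return threshold, curve


def stage_means(
    matrix: pd.DataFrame, design: Mapping[str, str], stage_order: Sequence[str]
) -> pd.DataFrame:
    """Aggregate a replicate-level matrix to stage level by the mean.

    ``design`` maps sample (column) names to stage labels; the output has one
    column per stage in ``stage_order``.
    """
    missing = [s for s in matrix.columns if s not in design]
    if missing:
        raise ValueError(f"samples missing from stage design: {missing}")
    cols = {}
    for stage in stage_order:
        members = [s for s in matrix.columns if design[s] == stage]
        if not members:
            raise ValueError(f"stage {stage!r} has no samples in the matrix")
        cols[stage] = matrix[members].mean(axis=1)
    return pd.DataFrame(cols, index=matrix.index)


def binarize_states(stage_signal: pd.DataFrame, threshold: float) -> StateMatrix:
    """Binarize stage-level signal: open (1) iff value >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    vals = stage_signal.to_numpy(dtype=float)
    if len(vals) and (vals < 0).any():
        raise ValueError("negative signal values: corrupted input")
    states = pd.DataFrame(
        (vals >= threshold).astype(np.int8),
        index=stage_signal.index,
        columns=stage_signal.columns,
    )
    return StateMatrix(states=states, threshold_used=float(threshold))
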