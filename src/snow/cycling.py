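"""Per-cell cycling detection by harmonic regression on generated series.

For each cell, the trained decoder generates a per-gene expression trajectory
on a uniform grid (default 24 points spanning 48 h), and each gene's series
is fit by ordinary least squares on [1, cos(2*pi*t/period), sin(2*pi*t/period)].
The fitted amplitude is sqrt(b_cos^2 + b_sin^2), the phase is the peak time of
the fitted cosine in hours within [0, period), and the p-value comes from the
F-test of the two harmonic coefficients against the intercept-only model.

Because the p-values are computed on *generated* (not observed) data, they
carry no calibrated error rate; they are priority scores for ranking genes
and cells, which is why no multiple-testing correction is applied and every
result carries that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import TimedCountData
from .flow_map import generate_timeseries
from .networks import TrainedModel

__all__ = ["CyclingResult", "harmonic_fit", "per_cell_cycling"]

P_VALUE_CAVEAT = (
    "p-values are computed on model-generated series; use them only to "
    "rank/prioritize genes, never as calibrated significance levels"
)


def _design(times: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi * times / period
    return np.column_stack([np.ones_like(times), np.cos(w), np.sin(w)])


def _harmonic_core(times: np.ndarray, Y: np.ndarray, period: float):
    """Vectorized OLS harmonic fit of columns of Y (n_times x n_series)."""
    n = times.size
    X = _design(times, period)
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient harmonic design (degenerate time grid)")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.sum(resid**2, axis=0)
    rss0 = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    amplitude = np.hypot(beta[1], beta[2])
    phase = (period / (2.0 * np.pi)) * np.arctan2(beta[2], beta[1]) % period
    dof = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss) / 2.0) / (rss / dof)
    p = stats.f.sf(F, 2, dof)
    # constant input: no variance at all -> amplitude 0, p 1 by convention
    degenerate = rss0 <= 1e-300
    p = np.where(degenerate, 1.0, p)
    amplitude = np.where(degenerate, 0.0, amplitude)
    phase = np.where(degenerate, 0.0, phase)
    # perfect harmonic fit (rss == 0, rss0 > 0): F -> inf, p -> 0
    p = np.where(~degenerate & (rss <= 1e-300), 0.0, p)
    return amplitude, phase, np.clip(p, 0.0, 1.0)


def harmonic_fit(times, values, period: float = 24.0):
    """Fit one series; returns (amplitude, phase_hours, p_value).

    Requires >= 4 points (one residual degree of freedom) on a
    non-degenerate grid.  The phase is the peak time of the fitted cosine
    after t = 0, in hours.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if times.size < 4:
        raise ValueError("harmonic fit needs at least 4 timepoints")
    if np.unique(times).size < 3:
        raise ValueError("times must span at least 3 distinct values")
    a, ph, p = _harmonic_core(times, values.reshape(-1, 1), period)
    return float(a[0]), float(ph[0]), float(p[0])


@dataclass
class CyclingResult:
    """Per cell x gene amplitude, phase (hours in [0, period)) and p-value."""

    amplitude: np.ndarray  # (C, G)
    phase_hours: np.ndarray  # (C, G)
    p_value: np.ndarray  # (C, G)
    cell_ids: np.ndarray
    gene_names: np.ndarray
    period: float
    grid: np.ndarray
    caveat: str = P_VALUE_CAVEAT

    def to_frame(self) -> pd.DataFrame:
        C, G = self.amplitude.shape
        return pd.DataFrame(
            {
                "cell": np.repeat(self.cell_ids, G),
                "gene": np.tile(self.gene_names, C),
                "amplitude": self.amplitude.ravel(),
                "phase_hours": self.phase_hours.ravel(),
                "p_value": self.p_value.ravel(),
            }
        )

    def mean_by_gene(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_names,
                "mean_p": self.p_value.mean(axis=0),
                "mean_amplitude": self.amplitude.mean(axis=0),
            }
        )


def per_cell_cycling(
    trained: TrainedModel,
    data: TimedCountData,
    n_points: int = 24,
    span_hours: float = 48.0,
    period: float = 24.0,
    l=None,
) -> CyclingResult:
    """Generate each cell's series on a uniform grid and fit every gene.

    The default scalar library size (the training reference) makes
    amplitudes comparable across cells.
    """
    grid = np.linspace(0.0, span_hours, n_points)
    series = generate_timeseries(
        trained, data=data, grid=grid, l=l if l is not None else trained.l_ref
    )
    C, T, G = series.values.shape
    Y = series.values.transpose(1, 0, 2).reshape(T, C * G)
    amp, phase, p = _harmonic_core(grid, Y, period)
    return CyclingResult(
        amplitude=amp.reshape(C, G),
        phase_hours=phase.reshape(C, G),
        p_value=p.reshape(C, G),
        cell_ids=series.cell_ids,
        gene_names=trained.gene_names,
        period=period,
        grid=grid,
    )
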