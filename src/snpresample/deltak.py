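"""Evanno-style ΔK peak statistic over an ordered resampling grid.

For grid points g₁ < g₂ < … < g_G with replicate means m(i) and replicate
standard deviations s(i) of some parameter, the interior points get

    ΔK(i) = |m(i−1) − 2·m(i) + m(i+1)| / s(i)

— the absolute second difference of the mean criterion, scaled by the
replicate dispersion at that point, exactly the construction used to locate
the knee of a saturating criterion curve.  The second difference is taken
on successive grid values regardless of their spacing.  End points have no
ΔK; interior points with s(i) = 0 are undefined (zero replicate variance
means the point is already exact) and are excluded from the peak search.

The recommended grid value is the argmax, with ties broken toward the
SMALLER value: the statistic's purpose is the minimal sufficient sample
size (or replicate count), so cost breaks the tie.  A flatness diagnostic
(max ΔK / median ΔK) makes "no clear peak" series visible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .resample import GridRun

__all__ = ["DeltaKSeries", "Recommendation", "delta_k_series", "recommend",
           "series_from_run"]

log = logging.getLogger(__name__)


@dataclass
class DeltaKSeries:
    """ΔK values over the interior of an ordered grid.

    ``grid`` holds the interior grid values; ``values`` the ΔK at each (NaN
    where undefined because the replicate SD was zero).  All defined values
    are ≥ 0 by construction.
    """

    grid: np.ndarray
    values: np.ndarray
    parameter: str = ""
    denominator: str = "sd"

    def defined(self) -> tuple[np.ndarray, np.ndarray]:
        ok = np.isfinite(self.values)
        return self.grid[ok], self.values[ok]


@dataclass
class Recommendation:
    """The grid value at the ΔK peak, with peak-quality diagnostics."""

    value: int
    peak_delta_k: float
    flatness: float  # max ΔK / median ΔK; ~1 means no clear peak
    tie: bool
    n_undefined: int


def delta_k_series(
    grid,
    means,
    sds,
    parameter: str = "",
    denominator: str = "sd",
    x=None,
) -> DeltaKSeries:
    """Compute the ΔK series from grid-ordered replicate means and SDs.

    ``denominator="sd"`` (default) scales by the SD of replicate values;
    ``"se"`` scales by SD/√x instead (``x`` = replicate counts, scalar or
    per-point).  The switch rescales every ΔK by √x at fixed x and never
    moves the within-series argmax, but changes comparability across series
    with different x.
    """
    grid = np.asarray(grid)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (len(grid) == len(means) == len(sds)):
        raise ValueError("grid, means and sds must have equal length")
    if len(grid) < 3:
        raise ValueError("ΔK needs at least 3 grid points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if denominator not in ("sd", "se"):
        raise ValueError("denominator must be 'sd' or 'se'")
    disp = sds.copy()
    if denominator == "se":
        if x is None:
            raise ValueError("denominator='se' requires replicate counts x")
        disp = sds / np.sqrt(np.asarray(x, dtype=float))

    second = np.abs(means[:-2] - 2.0 * means[1:-1] + means[2:])
    d_int = disp[1:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(d_int > 0.0, second / np.where(d_int > 0.0, d_int, 1.0),
                          np.nan)
    n_undef = int(np.isnan(values).sum())
    if n_undef:
        log.info("ΔK undefined at %d interior points (zero replicate SD)", n_undef)
    if not np.isfinite(values).any():
        raise ValueError("all interior ΔK points undefined (zero replicate SD)")
    return DeltaKSeries(grid[1:-1], values, parameter, denominator)


def recommend(series: DeltaKSeries) -> Recommendation:
    """Argmax of the ΔK series; ties go to the smaller grid value."""
    grid, vals = series.defined()
    if vals.size == 0:
        raise ValueError("series has no defined ΔK point")
    peak = float(vals.max())
    at_peak = grid[vals == peak]
    tie = at_peak.size > 1
    if tie:
        log.info("ΔK tie at %s; recommending the smallest (%s)",
                 list(at_peak), at_peak.min())
    med = float(np.median(vals))
    flatness = float("inf") if med == 0.0 and peak > 0.0 else (
        1.0 if peak == 0.0 else peak / med)
    n_undef = int(np.isnan(series.values).sum())
    return Recommendation(int(at_peak.min()), peak, flatness, tie, n_undef)


def series_from_run(run: GridRun, parameter: str,
                    denominator: str = "sd") -> DeltaKSeries:
    """ΔK series for one parameter of a :class:`~snpresample.resample.GridRun`."""
    grid, means, sds, x = run.series(parameter)
    return delta_k_series(grid, means, sds, parameter, denominator, x=x)
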