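"""Centering-fidelity statistics for SPB/nucleus trajectories and septum data.

Two scalar objectives score how well a cell centers its nucleus:

* reliability ``delta`` — absolute mean longitudinal displacement of the SPB
  from the geometric cell center (smaller = more reliable);
* robustness ``sigma_x`` — standard deviation of the longitudinal SPB position
  (smaller = more robust).

Because SPB positions are strongly autocorrelated in time, standard errors are
estimated with a moving-block bootstrap whose block size equals the
autocorrelation time of the series.

The failure coefficient ``Phi`` maps (delta, sigma_x) to the probability that
the SPB — approximated as Gaussian — lies beyond a failure threshold ``x_f``
(by convention the 95th percentile of absolute wild-type septum offsets).  Its
empirical counterpart ``S_f`` is the fraction of cells whose septum lies
farther than ``x_f`` from the cell center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.tsa.stattools import acf as _acf

from mtpush.simulator import Trajectory

__all__ = [
    "CenteringSummary",
    "FailureModel",
    "StationarityReport",
    "summarize",
    "autocorrelation_time",
    "moving_block_bootstrap_se",
    "failure_coefficient",
    "failure_threshold",
    "septum_failure_fraction",
    "z_score_features",
    "sphere_projection_convolve",
    "stationarity_check",
]


@dataclass(frozen=True)
class CenteringSummary:
    """delta / sigma summary of one trajectory with block-bootstrap SEs (um)."""

    delta: float
    sigma_x: float
    sigma_y: float
    se_delta: float
    se_sigma_x: float
    autocorr_time: float  # seconds
    n_samples: int


@dataclass(frozen=True)
class FailureModel:
    """Failure threshold ``xf`` (um) and the implied failure coefficient Phi."""

    xf: float
    phi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must be a probability")


def autocorrelation_time(series, dt: float = 1.0) -> float:
    """First 1/e crossing of the empirical autocorrelation function, seconds.

    Returns at least one sampling interval (white noise decorrelates within a
    sample); a constant series is defined as fully correlated and returns the
    record length.  For an AR(1) process with coefficient rho this estimates
    ``-dt / ln(rho)``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("series too short (need >= 10 samples)")
    if np.ptp(x) == 0.0:
        return x.size * dt
    nlags = min(x.size - 1, max(int(x.size // 2), 10))
    rho = _acf(x, nlags=nlags, fft=True)
    below = np.nonzero(rho < 1.0 / np.e)[0]
    lag = int(below[0]) if below.size else nlags
    return max(lag, 1) * dt


def moving_block_bootstrap_se(
    series,
    statistic,
    block: int,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """SE of ``statistic`` by resampling overlapping blocks with replacement.

    Blocks of ``block`` consecutive samples are drawn (overlapping, uniformly)
    and concatenated up to the original length; the SE is the standard
    deviation of the statistic across ``n_boot`` such resamples.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if block < 1:
        raise ValueError("block must be >= 1")
    if block > n:
        raise ValueError("block size exceeds series length")
    if n_boot < 2:
        raise ValueError("need n_boot >= 2")
    rng = np.random.default_rng() if rng is None else rng
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n - block + 1, size=(n_boot, n_blocks))
    offsets = np.arange(block)
    idx = (starts[:, :, None] + offsets[None, None, :]).reshape(n_boot, -1)[:, :n]
    reps = np.apply_along_axis(statistic, 1, x[idx])
    return float(np.std(reps, ddof=1))


def summarize(
    traj: Trajectory,
    burn_in: float = 0.0,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> CenteringSummary:
    """delta, sigma_x, sigma_y of the post-burn-in longitudinal SPB record.

    delta = |mean(x)| (cells are oriented so the time-averaged displacement is
    non-negative); sigma are sample standard deviations.  SEs use the
    moving-block bootstrap with block size equal to the autocorrelation time.
    Set ``n_boot=0`` to skip the bootstrap (SEs reported as NaN).
    """
    mask = traj.times >= burn_in
    x = np.asarray(traj.spb_x)[mask]
    y = np.asarray(traj.spb_y)[mask]
    if x.size == 0:
        raise ValueError("no samples after burn-in")
    delta = float(abs(np.mean(x)))
    sigma_x = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    sigma_y = float(np.std(y, ddof=1)) if y.size > 1 else 0.0
    if np.ptp(x) == 0.0:
        return CenteringSummary(delta, 0.0, sigma_y, 0.0, 0.0, x.size * traj.dt_out, x.size)
    act = autocorrelation_time(x, dt=traj.dt_out)
    block = max(int(round(act / traj.dt_out)), 1)
    if n_boot:
        rng = np.random.default_rng(0xB00) if rng is None else rng
        se_delta = moving_block_bootstrap_se(x, lambda s: abs(np.mean(s)), block, n_boot, rng)
        se_sigma = moving_block_bootstrap_se(x, lambda s: np.std(s, ddof=1), block, n_boot, rng)
    else:
        se_delta = se_sigma = float("nan")
    return CenteringSummary(delta, sigma_x, sigma_y, se_delta, se_sigma, act, int(x.size))


def failure_coefficient(delta: float, sigma_x: float, xf: float, two_sided: bool = False) -> float:
    """Gaussian-tail failure probability Phi = P(X > xf) for X ~ N(delta, sigma_x).

    One-sided by default (delta >= 0 by the orientation convention, so failures
    concentrate in the upper tail); the two-sided variant adds P(X < -xf).  At
    sigma_x = 0 the distribution is a point mass and Phi is an indicator.
    """
    if sigma_x < 0:
        raise ValueError("sigma_x must be >= 0")
    delta = abs(delta)
    if sigma_x == 0.0:
        return float(delta > xf)
    upper = sps.norm.sf((xf - delta) / sigma_x)
    if two_sided:
        upper += sps.norm.cdf((-xf - delta) / sigma_x)
    return float(min(upper, 1.0))


def failure_threshold(wt_septum_offsets, quantile: float = 0.05) -> float:
    """Failure threshold xf: the (1 - quantile) quantile of |septum offsets|.

    With the default quantile of 0.05 a failure is an event beyond the extreme
    5% of wild-type septum placements.
    """
    offs = np.abs(np.asarray(wt_septum_offsets, dtype=float))
    if offs.size == 0:
        raise ValueError("need at least one septum offset")
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    return float(np.quantile(offs, 1.0 - quantile))


def septum_failure_fraction(
    septum_offsets,
    xf: float,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Fraction S_f of cells with |septum offset| > xf, with case-resampling SE."""
    offs = np.abs(np.asarray(septum_offsets, dtype=float))
    if offs.size == 0:
        raise ValueError("need at least one septum offset")
    sf = float(np.mean(offs > xf))
    rng = np.random.default_rng(0x5F) if rng is None else rng
    reps = np.mean(offs[rng.integers(0, offs.size, size=(n_boot, offs.size))] > xf, axis=1)
    return sf, float(np.std(reps, ddof=1))


def z_score_features(mutant_features: pd.DataFrame, wt_features: pd.DataFrame) -> pd.Series:
    """Per-feature Z score: (mutant mean - WT mean) / WT standard deviation.

    Features whose WT standard deviation is zero are ill defined and reported
    as NaN (the hatched entries of a feature heat map).
    """
    shared = [c for c in mutant_features.columns if c in wt_features.columns]
    if not shared:
        raise ValueError("no shared feature columns")
    out = {}
    for c in shared:
        sd = float(wt_features[c].std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            out[c] = np.nan
        else:
            out[c] = (float(mutant_features[c].mean()) - float(wt_features[c].mean())) / sd
    return pd.Series(out, name="z_score")


def sphere_projection_convolve(
    centroid_x_samples,
    radius: float,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Density of the axis projection of a point uniform on a sphere of given
    radius centered at each sampled centroid.

    By Archimedes' hat-box theorem the projection of the uniform distribution
    on a sphere onto an axis is uniform on [-radius, +radius]; the SPB position
    distribution is therefore the centroid distribution convolved with that
    box.  Returns ``(grid, density)`` with unit total mass on the grid.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    s = np.asarray(centroid_x_samples, dtype=float)
    if grid is None:
        lo, hi = s.min() - 2 * radius, s.max() + 2 * radius
        grid = np.linspace(lo, hi, 512)
    # mean over samples of the box kernel 1/(2r) on [s - r, s + r], via
    # sorted counts (avoids the n-by-grid broadcast)
    s_sorted = np.sort(s)
    hi = np.searchsorted(s_sorted, grid + radius, side="right")
    lo = np.searchsorted(s_sorted, grid - radius, side="left")
    dens = (hi - lo) / (s.size * 2.0 * radius)
    return grid, dens


@dataclass(frozen=True)
class StationarityReport:
    window_means: np.ndarray
    window_vars: np.ndarray
    mean_slope: float
    mean_slope_ci: tuple[float, float]
    var_slope: float
    var_slope_ci: tuple[float, float]
    stationary: bool


def _slope_with_ci(values, n_boot: int, rng: np.random.Generator) -> tuple[float, tuple[float, float]]:
    k = len(values)
    idx = np.arange(k, dtype=float)
    slope = float(np.polyfit(idx, values, 1)[0])
    reps = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, k, size=k)
        if np.ptp(idx[pick]) == 0:  # degenerate resample: slope undefined
            reps[b] = 0.0
        else:
            reps[b] = np.polyfit(idx[pick], np.asarray(values)[pick], 1)[0]
    return slope, (float(np.quantile(reps, 0.025)), float(np.quantile(reps, 0.975)))


def stationarity_check(
    series,
    n_windows: int = 6,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
) -> StationarityReport:
    """Windowed-moment stationarity diagnostic.

    The series is split into ``n_windows`` equal windows; the slopes of the
    windowed means and variances against the window index are reported with a
    case-resampling bootstrap CI.  The series is flagged non-stationary when
    either CI excludes zero.
    """
    x = np.asarray(series, dtype=float)
    if n_windows < 3:
        raise ValueError("need n_windows >= 3")
    if x.size < 2 * n_windows:
        raise ValueError("series too short for the requested windows")
    rng = np.random.default_rng(0x57A7) if rng is None else rng
    chunks = np.array_split(x, n_windows)
    means = np.array([c.mean() for c in chunks])
    vars_ = np.array([c.var(ddof=1) for c in chunks])
    m_slope, m_ci = _slope_with_ci(means, n_boot, rng)
    v_slope, v_ci = _slope_with_ci(vars_, n_boot, rng)
    stationary = (m_ci[0] <= 0.0 <= m_ci[1]) and (v_ci[0] <= 0.0 <= v_ci[1])
    return StationarityReport(means, vars_, m_slope, m_ci, v_slope, v_ci, stationary)
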