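"""Synthetic-data generators standing in for the microscopy-derived inputs.

Each generator is reproducible from (parameters, n, seed) and produces data in
the same containers the analysis modules consume:

* catastrophe-time datasets: Gamma(N, T) samples observed through a min/max
  truncation window (only events inside the observable window are scored);
  the default calibration mimics the reference (Mal3) dataset, shape 3.6 and
  timescale 35 s with a (10, 400) s window;
* SPB trajectories: stationary first-order autoregressive (AR(1)) series with
  a prescribed mean offset, standard deviation, and autocorrelation time — the
  simplest process with the statistical structure (stationarity plus
  autocorrelation) the statistics layer assumes, which lets that layer be
  tested independently of the mechanistic simulator;
* septum offsets: folded Gaussians combining nucleus-position spread with
  septum placement noise;
* cell-length populations: truncated normals used to drive per-replicate cell
  geometry.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from mtpush.bayes import CatastropheDataset
from mtpush.simulator import Trajectory

__all__ = [
    "MAL3_CALIBRATION",
    "gen_catastrophe_times",
    "gen_spb_trajectory",
    "gen_septum_offsets",
    "gen_cell_lengths",
]

#: Reference catastrophe-time calibration: gamma shape, timescale (s), window (s).
MAL3_CALIBRATION = {"shape": 3.6, "scale": 35.0, "window": (10.0, 400.0)}


def gen_catastrophe_times(
    shape: float = MAL3_CALIBRATION["shape"],
    scale: float = MAL3_CALIBRATION["scale"],
    window: tuple[float, float] = MAL3_CALIBRATION["window"],
    n: int = 200,
    seed: int = 0,
) -> CatastropheDataset:
    """Gamma(shape, scale) catastrophe times rejection-sampled into the window.

    Sampling rejects draws outside [window[0], window[1]] until ``n`` are
    accepted, which is exactly the window-truncated gamma law.  Errors out if
    the acceptance probability is below 1e-3 (pathological window).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a, b = window
    if not (0 <= a < b):
        raise ValueError("window must satisfy 0 <= a < b")
    dist = stats.gamma(a=shape, scale=scale)
    accept = (dist.cdf(b) if np.isfinite(b) else 1.0) - dist.cdf(a)
    if accept < 1e-3:
        raise ValueError(f"window acceptance probability {accept:.2e} < 1e-3")
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < n:
        batch = rng.gamma(shape, scale, size=max(int(1.5 * (n - out.size) / accept), 64))
        out = np.concatenate([out, batch[(batch >= a) & (batch <= b)]])
    return CatastropheDataset(times=out[:n], window=(a, b))


def gen_spb_trajectory(
    mean_offset: float,
    sd: float,
    ac_time: float,
    dt: float = 1.0,
    duration: float = 7200.0,
    seed: int = 0,
) -> Trajectory:
    """Stationary AR(1) surrogate SPB track.

    x has stationary mean ``mean_offset``, stationary standard deviation
    ``sd`` and autocorrelation time ``ac_time`` (lag-1 coefficient
    ``exp(-dt / ac_time)``); y is an independent AR(1) with mean 0 and the same
    sd and ac_time.  Initial values are drawn from the stationary law, so the
    whole record is stationary.  The SPB columns coincide with (x, y): the
    surrogate models the SPB directly, there is no underlying nucleus.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if ac_time < dt:
        raise ValueError("ac_time must be >= dt")
    n = int(round(duration / dt)) + 1
    times = np.arange(n) * dt
    rng = np.random.default_rng(seed)
    if sd == 0.0:
        x = np.full(n, mean_offset)
        y = np.zeros(n)
    else:
        phi = math.exp(-dt / ac_time)
        innov_sd = sd * math.sqrt(1.0 - phi * phi)
        eps = rng.normal(0.0, innov_sd, size=(2, n))
        x = np.empty(n)
        y = np.empty(n)
        x[0] = rng.normal(mean_offset, sd)
        y[0] = rng.normal(0.0, sd)
        for k in range(1, n):
            x[k] = mean_offset + phi * (x[k - 1] - mean_offset) + eps[0, k]
            y[k] = phi * y[k - 1] + eps[1, k]
    return Trajectory(
        times=times,
        x=x,
        y=y,
        omega=np.zeros(n),
        spb_x=x,
        spb_y=y,
        dt_out=dt,
        seed=seed,
    )


def gen_septum_offsets(
    delta: float,
    sigma: float,
    placement_noise: float = 0.2,
    n: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Unsigned septum offsets |N(delta, sqrt(sigma^2 + placement_noise^2))|.

    The septum is laid down at the nucleus position plus independent placement
    noise; offsets are reported as absolute distances from the cell center.
    """
    if sigma < 0 or placement_noise < 0:
        raise ValueError("sigma and placement_noise must be >= 0")
    rng = np.random.default_rng(seed)
    total_sd = math.hypot(sigma, placement_noise)
    return np.abs(rng.normal(delta, total_sd, size=n)) if total_sd > 0 else np.full(n, abs(delta))


def gen_cell_lengths(
    mean: float = 14.0,
    sd: float = 1.0,
    bounds: tuple[float, float] = (8.0, 24.0),
    n: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Truncated-normal cell lengths (2L, um) emulating population variation."""
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must be ordered and positive")
    if sd == 0.0:
        if not (lo <= mean <= hi):
            raise ValueError("mean outside bounds with sd = 0")
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    rng = np.random.default_rng(seed)
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
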