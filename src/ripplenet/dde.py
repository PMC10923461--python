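"""Numerical integration of the Gaussian-drift delay differential equation.

In the mean-field limit the membrane-potential density is approximated
by a Gaussian of fixed variance D whose mean mu obeys

    tau_m mu'(t) = I_E(t) - tau_m K r(t - Delta) - mu(t),
    r(t) = [mu'(t)]_+  exp(-(V_T - mu(t))^2 / 2D) / sqrt(2 pi D),

i.e. the population rate is the drift current of the Gaussian across
threshold, clipped at zero for downward drift.  An optional
phenomenological population reset drops mu instantaneously to
``mu_reset = mu_max - (V_T - V_R) s`` at the end of each population
spike, where s is the suprathreshold Gaussian mass (saturation).

Depending on the constant drive the DDE shows four regimes: a stable
zero-rate fixed point, pathological fast oscillations at ~1/(2 Delta),
period-2 oscillations, and regular period-1 oscillations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .drive import DriveProfile, constant_drive
from .params import as_dimensionless


class Regime(str, Enum):
    FIXED_POINT = "fixed point"
    PATHOLOGICAL = "pathological fast oscillation"
    PERIOD_2 = "period-2 oscillation"
    PERIOD_1 = "period-1 oscillation"


@dataclass
class DDETrajectory:
    """Forward-Euler trajectory of the Gaussian-drift DDE."""

    t: np.ndarray            # ms
    mu: np.ndarray           # mean membrane potential (dimensionless)
    r: np.ndarray            # rate in 1/ms (dimensionless voltage crossing)
    drive: np.ndarray        # I_E(t)
    reset_times: np.ndarray  # ms
    reset_values: np.ndarray # (mu_max, mu_reset) pairs
    dt: float
    params: object
    with_reset: bool
    boundary_flag: bool = False

    @property
    def rate_hz(self) -> np.ndarray:
        """Population rate in Hz (per-ms rate times 1000)."""
        return self.r * 1000.0

    def save(self, path) -> None:
        np.savetxt(path, np.column_stack([self.t, self.mu, self.r, self.drive]),
                   header="t_ms mu rate_per_ms drive")


def integrate_dde(params, drive, duration: float | None = None,
                  dt: float = 0.005, mu_history: float = -1.0,
                  with_reset: bool = False) -> DDETrajectory:
    """Forward-Euler integration of the Gaussian-drift DDE.

    ``mu_history`` is the constant value of mu on [-Delta, 0]; it should
    be well below threshold so the initial rate is ~0.  After each
    detected population-spike end (mu' changing sign + -> - with a
    preceding rate excursion) the reset drops mu to mu_reset and the
    rate is clipped to zero for one delay, suppressing the spurious
    rebound of [mu']_+ right after the reset.
    """
    p = as_dimensionless(params)
    if not isinstance(drive, DriveProfile):
        if duration is None:
            raise ValueError("duration required with a scalar drive")
        drive = constant_drive(float(drive), duration)
    if duration is None:
        duration = drive.t_end - drive.t_start

    n_delay = int(round(p.delta / dt))
    if abs(n_delay * dt - p.delta) > 1e-9:
        warnings.warn(f"delay {p.delta} ms rounded to {n_delay} steps of {dt} ms")
    n = int(round(duration / dt))
    sq = math.sqrt(2.0 * math.pi * p.D)

    t = drive.t_start + np.arange(n + 1) * dt
    I_E = np.asarray(drive(np.minimum(t, drive.t_end)))
    mu = np.empty(n + 1)
    r = np.zeros(n + 1)
    mud = np.zeros(n + 1)
    mu[0] = mu_history
    clip_until = -1
    rtimes: list[float] = []
    rvals: list[tuple[float, float]] = []
    rate_floor = 1e-6

    for k in range(n):
        r_del = r[k - n_delay] if k >= n_delay else 0.0
        mud[k] = (I_E[k] - p.tau_m * p.K * r_del - mu[k]) / p.tau_m
        rr = 0.0
        if mud[k] > 0 and k > clip_until:
            rr = mud[k] * math.exp(-(p.V_T - mu[k]) ** 2 / (2.0 * p.D)) / sq
        r[k] = rr
        mu[k + 1] = mu[k] + dt * mud[k]
        if not math.isfinite(mu[k + 1]):
            raise FloatingPointError(f"non-finite DDE state at t={t[k]:.3f} ms")
        if (with_reset and k > 0 and k > clip_until
                and mud[k - 1] > 0 and mud[k] <= 0
                and r[max(0, k - 2 * n_delay):k].max() > rate_floor):
            mu_max = mu[k]
            s = 0.5 * (1.0 + math.erf((mu_max - p.V_T) / math.sqrt(2.0 * p.D)))
            mu_reset = mu_max - (p.V_T - p.V_R) * s
            mu[k + 1] = mu_reset
            clip_until = k + n_delay
            rtimes.append(t[k])
            rvals.append((mu_max, mu_reset))

    return DDETrajectory(
        t=t, mu=mu, r=r, drive=I_E,
        reset_times=np.asarray(rtimes), reset_values=np.asarray(rvals),
        dt=dt, params=p, with_reset=with_reset)


def _rate_peaks(traj: DDETrajectory, discard_ms: float):
    from scipy.signal import find_peaks
    sel = traj.t >= traj.t[0] + discard_ms
    rr = traj.r[sel]
    tt = traj.t[sel]
    if rr.size == 0 or rr.max() <= 0:
        return tt, rr, np.empty(0, dtype=int)
    # minimum separation of half a delay suppresses plateau-shaped double
    # detections within one population spike
    min_dist = max(1, int(round(0.5 * traj.params.delta / traj.dt)))
    peaks, _ = find_peaks(rr, height=0.05 * rr.max(), distance=min_dist)
    return tt, rr, peaks


def classify_regime(traj: DDETrajectory, discard_ms: float = 100.0,
                    rate_floor: float = 1e-4,
                    period2_ratio: float = 1.05) -> tuple[Regime, bool]:
    """Label the post-transient dynamics of a constant-drive trajectory.

    Returns (label, boundary_flag); the flag marks near-threshold
    classifications that may flip with small parameter changes.
    """
    p = traj.params
    tt, rr, peaks = _rate_peaks(traj, discard_ms)
    if rr.size == 0:
        raise ValueError("trajectory shorter than the discard window")
    if rr.max() < rate_floor or peaks.size < 3:
        return Regime.FIXED_POINT, rr.max() > 0.1 * rate_floor
    periods = np.diff(tt[peaks])
    period = float(np.median(periods))
    heights = rr[peaks]
    # alternate-cycle amplitude comparison for period-2
    h_even = heights[:-1:2].mean() if heights[:-1:2].size else heights.mean()
    h_odd = heights[1::2].mean() if heights[1::2].size else heights.mean()
    ratio = max(h_even, h_odd) / max(min(h_even, h_odd), 1e-300)
    mu_sel = traj.mu[traj.t >= traj.t[0] + discard_ms]
    mu_min = float(mu_sel.min())
    shallow = mu_min > p.V_T - 3.0 * math.sqrt(p.D)
    near_2delta = abs(period - 2 * p.delta) < 0.25 * p.delta
    if shallow and near_2delta:
        return Regime.PATHOLOGICAL, False
    if ratio > period2_ratio:
        return Regime.PERIOD_2, ratio < period2_ratio * 1.2
    boundary = shallow != near_2delta
    return Regime.PERIOD_1, boundary


def oscillation_frequency(traj: DDETrajectory, discard_ms: float = 100.0) -> float:
    """Dominant oscillation frequency (Hz) from median peak spacing."""
    tt, rr, peaks = _rate_peaks(traj, discard_ms)
    if peaks.size < 3:
        return float("nan")
    return 1000.0 / float(np.median(np.diff(tt[peaks])))


def dde_bifurcation(params, lo: float = 0.3, hi: float = 1.0,
                    tol: float = 1e-3, duration: float = 400.0,
                    dt: float = 0.005) -> float:
    """Drive at which the DDE fixed point gives way to oscillations.

    Bisection on constant drive between a fixed-point and an oscillatory
    classification of the (no-reset) forward-Euler trajectory.
    """
    def oscillates(I_E: float) -> bool:
        traj = integrate_dde(params, I_E, duration=duration, dt=dt)
        label, _ = classify_regime(traj)
        return label is not Regime.FIXED_POINT

    if oscillates(lo) or not oscillates(hi):
        raise ValueError(f"[{lo}, {hi}] does not bracket the transition")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if oscillates(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


__all__ = ["Regime", "DDETrajectory", "integrate_dde", "classify_regime",
           "oscillation_frequency", "dde_bifurcation"]
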