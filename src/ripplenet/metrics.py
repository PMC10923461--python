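"""Ripple quantification: network frequency, unit statistics, saturation,
instantaneous frequency and the IFA slope.

The asymptotic network frequency at constant drive is the location of
the dominant peak of the population-rate power spectral density.  Under
time-varying drive two instantaneous-frequency estimators are provided:

* a continuous estimate from a complex-Morlet wavelet spectrogram
  (argmax of power above a 70 Hz floor), and
* a discrete estimate from the inverse peak-to-peak distances of the
  smoothed population rate.

Both flag estimates as valid only where the signal exceeds a baseline
mean + 4 SD threshold.  Intra-ripple frequency accommodation (IFA) is
the ordinary least-squares slope chi_IFA of pooled valid (time,
frequency) points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass
class InstFreqSeries:
    """Discrete instantaneous-frequency estimates for one run."""

    t: np.ndarray            # ms
    f: np.ndarray            # Hz
    power: np.ndarray        # spectral power or peak height
    valid: np.ndarray        # boolean mask
    estimator: str = "peaks"
    threshold: float = np.nan

    def __post_init__(self) -> None:
        order = np.argsort(self.t)
        for name in ("t", "f", "power", "valid"):
            setattr(self, name, np.asarray(getattr(self, name))[order])


@dataclass(frozen=True)
class IfaFit:
    """Pooled linear regression of instantaneous frequency on time."""

    chi_ifa: float           # Hz/ms
    intercept: float         # Hz
    n_points: int
    n_runs: int = 1


def network_frequency_psd(rate, dt: float, f_min: float = 30.0,
                          f_max: float = 1000.0, nperseg_ms: float = 500.0,
                          peak_snr: float = 5.0):
    """Dominant PSD peak of a constant-drive population rate.

    Parameters
    ----------
    rate : array, Hz, sampled at ``dt`` ms.
    peak_snr : minimum ratio of the peak to the median in-band power for
        the estimate to count as a genuine oscillation peak.

    Returns (frequency_hz or nan, valid_flag).
    """
    rate = np.asarray(rate, dtype=float)
    fs = 1000.0 / dt  # Hz
    nper = min(rate.size, int(nperseg_ms / dt))
    freqs, psd = signal.welch(rate - rate.mean(), fs=fs, nperseg=nper)
    band = (freqs >= f_min) & (freqs <= f_max)
    if not np.any(band) or np.all(psd[band] == 0):
        return float("nan"), False
    fb, pb = freqs[band], psd[band]
    i = int(np.argmax(pb))
    valid = pb[i] > peak_snr * np.median(pb)
    return float(fb[i]), bool(valid)


def unit_stats(spike_units, spike_times, duration: float, N: int):
    """Mean unit firing rate (Hz) and mean per-unit CV of the ISIs.

    The CV is computed per unit over its inter-spike intervals and then
    averaged over units with at least two ISIs; ``duration`` in ms.
    """
    spike_units = np.asarray(spike_units)
    spike_times = np.asarray(spike_times, dtype=float)
    f_unit = spike_times.size / N / (duration * 1e-3)
    cvs = []
    order = np.lexsort((spike_times, spike_units))
    u_sorted = spike_units[order]
    t_sorted = spike_times[order]
    bounds = np.flatnonzero(np.diff(u_sorted)) + 1
    for tr in np.split(t_sorted, bounds):
        if tr.size >= 3:
            isi = np.diff(tr)
            m = isi.mean()
            if m > 0:
                cvs.append(isi.std() / m)
    cv = float(np.mean(cvs)) if cvs else float("nan")
    return float(f_unit), cv


def saturation(f_unit: float, f_net: float) -> float:
    """Fraction of units firing per population cycle, s = f_unit/f_net."""
    if f_net <= 0:
        raise ValueError("f_net must be positive")
    return f_unit / f_net


def full_synchrony_point(drives, saturations) -> float:
    """Drive at which the saturation curve crosses 1 (linear interpolation).

    ``drives`` must be increasing; the saturation curve must bracket 1
    (or already start at/above 1, in which case the lowest such drive is
    returned).
    """
    drives = np.asarray(drives, dtype=float)
    sats = np.asarray(saturations, dtype=float)
    if np.any(np.diff(drives) <= 0):
        raise ValueError("drives must be strictly increasing")
    if sats[0] >= 1.0:
        return float(drives[0])
    above = np.flatnonzero(sats >= 1.0)
    if above.size == 0:
        raise ValueError("saturation curve does not reach 1 (no bracket)")
    j = above[0]
    x0, x1, s0, s1 = drives[j - 1], drives[j], sats[j - 1], sats[j]
    return float(x0 + (1.0 - s0) * (x1 - x0) / (s1 - s0))


def _baseline_stats(x, t, baseline_window):
    lo, hi = baseline_window
    sel = (t >= lo) & (t < hi)
    if not np.any(sel):
        raise ValueError("empty baseline window")
    return float(np.mean(x[sel])), float(np.std(x[sel]))


def inst_freq_peaks(rate_smooth, dt: float, baseline_window,
                    t_start: float = 0.0, window=None,
                    min_separation: float = 2.5,
                    threshold: float | None = None) -> InstFreqSeries:
    """Discrete instantaneous frequency from peak-to-peak distances.

    Only peaks more than 4 SD above the mean baseline rate count.  Each
    frequency 1/(t[k+1]-t[k]) is assigned to the midpoint of the peak
    pair (symmetric under time reversal).  ``window`` optionally
    restricts the analysis to the stimulation epoch (baseline segments
    of small networks can produce spurious super-threshold fluctuation
    peaks).
    """
    rate_smooth = np.asarray(rate_smooth, dtype=float)
    t = t_start + np.arange(rate_smooth.size) * dt
    if threshold is not None:
        thresh = float(threshold)
    else:
        mu, sd = _baseline_stats(rate_smooth, t, baseline_window)
        thresh = mu + 4.0 * sd
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        rate_w, t_w = rate_smooth[sel], t[sel]
    else:
        rate_w, t_w = rate_smooth, t
    distance = max(1, int(round(min_separation / dt)))
    peaks, props = signal.find_peaks(rate_w, height=thresh, distance=distance)
    if peaks.size < 2:
        return InstFreqSeries(np.empty(0), np.empty(0), np.empty(0),
                              np.empty(0, bool), "peaks", thresh)
    tp = t_w[peaks]
    heights = props["peak_heights"]
    f = 1000.0 / np.diff(tp)               # ms -> Hz
    tm = 0.5 * (tp[1:] + tp[:-1])
    power = np.minimum(heights[1:], heights[:-1])
    return InstFreqSeries(tm, f, power, np.ones(f.size, bool), "peaks", thresh)


def inst_freq_spectrogram(rate, dt: float, baseline_window,
                          t_start: float = 0.0, f_min: float = 70.0,
                          f_max: float = 350.0, n_freq: int = 90,
                          wavelet: str = "cmor1.5-1.0",
                          threshold: float | None = None) -> InstFreqSeries:
    """Continuous instantaneous frequency from a complex-Morlet wavelet
    spectrogram: per time step, the frequency above ``f_min`` with
    maximal instantaneous power.  Points are valid where that power
    exceeds the baseline 0-Hz mean power + 4 SD."""
    import pywt

    rate = np.asarray(rate, dtype=float)
    t = t_start + np.arange(rate.size) * dt
    fs = 1000.0 / dt
    freqs = np.linspace(max(f_min, 1.0), f_max, n_freq)
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    coeffs, _ = pywt.cwt(rate - rate.mean(), scales, wavelet,
                         sampling_period=dt / 1000.0)
    power = np.abs(coeffs) ** 2            # (n_freq, n_time)
    imax = np.argmax(power, axis=0)
    pmax = power[imax, np.arange(power.shape[1])]
    fhat = freqs[imax]
    if threshold is not None:
        thresh = float(threshold)
    else:
        mu, sd = _baseline_stats(pmax, t, baseline_window)
        thresh = mu + 4.0 * sd
    valid = pmax > thresh
    return InstFreqSeries(t, fhat, pmax, valid, "spectrogram", thresh)


def ifa_slope(series) -> IfaFit:
    """Pooled OLS slope chi_IFA = Cov(f, t)/Var(t) over valid points."""
    if isinstance(series, InstFreqSeries):
        series = [series]
    ts, fs = [], []
    for s in series:
        ts.append(s.t[s.valid])
        fs.append(s.f[s.valid])
    t = np.concatenate(ts)
    f = np.concatenate(fs)
    if t.size < 3:
        raise ValueError("need at least 3 pooled valid points")
    if np.var(t) == 0:
        raise ValueError("degenerate time values (zero variance)")
    slope = float(np.cov(f, t)[0, 1] / np.var(t, ddof=1))
    intercept = float(f.mean() - slope * t.mean())
    return IfaFit(chi_ifa=slope, intercept=intercept,
                  n_points=int(t.size), n_runs=len(series))


__all__ = ["InstFreqSeries", "IfaFit", "network_frequency_psd", "unit_stats",
           "saturation", "full_synchrony_point", "inst_freq_peaks",
           "inst_freq_spectrogram", "ifa_slope"]
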