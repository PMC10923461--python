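"""Spiking simulation of the delayed-pulse-coupled noisy LIF network.

The network is fully connected (self-coupling included): every spike is
broadcast to all N units and arrives exactly one synaptic delay later
as an instantaneous voltage decrement of size K/N (dimensionless).
Integration is Euler--Maruyama on the rescaled voltage equation

    tau_m dV_i = (I_E(t) - V_i) dt + sqrt(2 D tau_m) dW_i  -  kicks,

with instantaneous threshold-and-reset at V_T = 1 -> V_R and no
refractory period.  A unit that is at or above threshold at the end of
a step emits one spike timestamped at that step and is reset within the
same step.  Delayed arrivals are handled through a ring buffer of
per-step population spike counts and are applied additively before the
threshold check of the arrival step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drive import DriveProfile, constant_drive
from .params import DimensionlessParams, as_dimensionless


@dataclass
class SimResult:
    """Outcome of one spiking-network run (times in ms, rates in Hz)."""

    spike_units: np.ndarray          # unit index per spike
    spike_times: np.ndarray          # spike time per spike, ms
    counts: np.ndarray               # population spike count per step
    t: np.ndarray                    # bin left edges, ms
    rate_raw: np.ndarray             # empirical population rate, Hz
    rate_smooth: np.ndarray          # Gaussian-smoothed rate, Hz
    mean_voltage: np.ndarray         # population-mean voltage per step
    dt: float
    seed: int
    params: DimensionlessParams
    drive: DriveProfile
    snapshot_t: np.ndarray | None = None
    snapshots: np.ndarray | None = None   # (n_snapshots, N) voltages

    @property
    def duration(self) -> float:
        return float(self.t[-1] + self.dt)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def save(self, prefix) -> None:
        """Write raster, rates and metadata as plain-text files."""
        import json
        from dataclasses import asdict
        np.savetxt(f"{prefix}.raster.txt",
                   np.column_stack([self.spike_units, self.spike_times]),
                   fmt="%d %.5f", header="unit_id t_ms")
        np.savetxt(f"{prefix}.rate.txt",
                   np.column_stack([self.t, self.rate_raw, self.rate_smooth]),
                   header="t_ms rate_hz rate_smooth_hz")
        meta = {"dt": self.dt, "seed": self.seed,
                "params": asdict(self.params),
                "drive_segments": list(map(list, self.drive.segments)),
                "drive_units": self.drive.units,
                "n_spikes": self.n_spikes}
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=1)


def simulate(params, drive, duration: float | None = None, dt: float = 0.01,
             seed: int = 0, record_snapshots: bool = False,
             snapshot_stride_ms: float = 0.1,
             sigma_t: float = 0.3) -> SimResult:
    """Run the spiking network.

    Parameters
    ----------
    params : DimensionlessParams or PhysicalParams
        Physical sets are converted on entry; the integration always
        runs in dimensionless voltage.
    drive : DriveProfile or float
        Drive time course in dimensionless units (a bare float is a
        constant drive held for ``duration``).
    duration : float, ms
        Defaults to the drive profile's span.
    dt : float, ms
        Euler--Maruyama step.
    seed : int
        Seed for the one NumPy generator driving initial conditions
        and the per-step noise.
    """
    p = as_dimensionless(params)
    if not isinstance(drive, DriveProfile):
        if duration is None:
            raise ValueError("duration required for a constant drive value")
        drive = constant_drive(float(drive), duration)
    if duration is None:
        duration = drive.t_end - drive.t_start
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_delay = int(round(p.delta / dt))
    if abs(n_delay * dt - p.delta) > 1e-9:
        import warnings
        warnings.warn(f"delay {p.delta} ms rounded to {n_delay} steps of {dt} ms")
    if duration < p.delta:
        raise ValueError("duration must be at least one synaptic delay")

    n_steps = int(round(duration / dt))
    N = p.N
    rng = np.random.default_rng(seed)

    v = rng.uniform(p.V_R, p.V_T, size=N)
    t_grid = drive.t_start + np.arange(n_steps) * dt
    I_E = drive.sample(dt)[1][:n_steps] if n_steps > 1 else np.array([drive(t_grid[0])])
    if I_E.size < n_steps:  # guard for rounding at the profile end
        I_E = np.pad(I_E, (0, n_steps - I_E.size), mode="edge")

    counts = np.zeros(n_steps, dtype=np.int64)
    mean_v = np.empty(n_steps)
    spike_units: list[np.ndarray] = []
    spike_steps: list[np.ndarray] = []

    kick = p.K / N
    noise_amp = np.sqrt(2.0 * p.D * dt / p.tau_m)
    dt_over_tau = dt / p.tau_m

    snap_stride = max(1, int(round(snapshot_stride_ms / dt)))
    snaps: list[np.ndarray] = []
    snap_t: list[float] = []

    # chunked noise to amortize RNG call overhead
    chunk = max(1, min(n_steps, int(4e6 // max(N, 1)) or 1))
    noise_block = None
    block_start = 0

    for k in range(n_steps):
        if noise_block is None or k >= block_start + noise_block.shape[0]:
            block_start = k
            noise_block = rng.standard_normal((min(chunk, n_steps - k), N))
        xi = noise_block[k - block_start]

        dv = dt_over_tau * (I_E[k] - v)
        if k >= n_delay and counts[k - n_delay]:
            dv = dv - kick * counts[k - n_delay]
        v += dv
        v += noise_amp * xi

        fired = v >= p.V_T
        n_f = int(np.count_nonzero(fired))
        if n_f:
            counts[k] = n_f
            idx = np.nonzero(fired)[0]
            spike_units.append(idx)
            spike_steps.append(np.full(n_f, k, dtype=np.int64))
            v[idx] = p.V_R
        mean_v[k] = v.mean()
        if record_snapshots and k % snap_stride == 0:
            snaps.append(v.copy())
            snap_t.append(t_grid[k])
        if not np.isfinite(mean_v[k]):
            raise FloatingPointError(
                f"non-finite voltages at t={t_grid[k]:.3f} ms; "
                "drive too extreme for this dt")

    units = np.concatenate(spike_units) if spike_units else np.empty(0, dtype=np.int64)
    steps = np.concatenate(spike_steps) if spike_steps else np.empty(0, dtype=np.int64)
    times = t_grid[0] + (steps + 1) * dt

    rate_raw = counts / (N * dt * 1e-3)  # spikes/s
    rate_smooth = smooth_rate(rate_raw, sigma_t, dt)
    return SimResult(
        spike_units=units, spike_times=times, counts=counts, t=t_grid,
        rate_raw=rate_raw, rate_smooth=rate_smooth, mean_voltage=mean_v,
        dt=dt, seed=seed, params=p, drive=drive,
        snapshot_t=np.asarray(snap_t) if record_snapshots else None,
        snapshots=np.asarray(snaps) if record_snapshots else None,
    )


def population_rate(spike_times, N: int, dt: float, t_start: float = 0.0,
                    duration: float | None = None):
    """Empirical population rate: per-bin spike count / (N * dt).

    ``spike_times`` in ms; returns (bin left edges ms, rate in spikes/s).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if duration is None:
        duration = (spike_times.max() - t_start) if spike_times.size else dt
    n_bins = max(1, int(np.ceil(duration / dt - 1e-9)))
    edges = t_start + np.arange(n_bins + 1) * dt
    counts, _ = np.histogram(spike_times, bins=edges)
    return edges[:-1], counts / (N * dt * 1e-3)


def smooth_rate(rate, sigma_t: float, dt: float):
    """Convolve a rate trace with a normalized Gaussian of SD ``sigma_t``
    ms, truncated at +-5 sigma.  Area-preserving away from the edges."""
    if sigma_t <= 0:
        raise ValueError("sigma_t must be positive")
    rate = np.asarray(rate, dtype=float)
    half = int(np.ceil(5.0 * sigma_t / dt))
    x = np.arange(-half, half + 1) * dt
    kernel = np.exp(-0.5 * (x / sigma_t) ** 2)
    kernel /= kernel.sum()
    return np.convolve(rate, kernel, mode="same")


@dataclass
class PopulationCycleAverage:
    """Phase-binned average of one oscillation cycle."""

    phase: np.ndarray          # bin centers in [0, 2 pi)
    rate: np.ndarray           # mean rate per phase bin, Hz
    mean_voltage: np.ndarray   # mean membrane potential per bin
    voltage_std: np.ndarray    # SD of voltage distribution per bin
    voltage_edges: np.ndarray | None = None
    voltage_hist: np.ndarray | None = None  # (n_bins, n_voltage_bins)
    n_cycles: int = 0


def average_cycle(sim: SimResult, n_bins: int = 21, discard_ms: float = 50.0,
                  phase_offset: float = 0.0) -> PopulationCycleAverage:
    """Average oscillation cycle, segmented by the phase of the analytic
    signal (Hilbert transform) of the population-mean membrane potential.

    Requires a constant-drive oscillatory run; voltage histograms are
    only produced when the run recorded snapshots.
    """
    from scipy.signal import hilbert

    keep = sim.t >= sim.t[0] + discard_ms
    mv = sim.mean_voltage[keep]
    t = sim.t[keep]
    analytic = hilbert(mv - mv.mean())
    phase_offset = phase_offset % (2 * np.pi)
    phase = np.mod(np.unwrap(np.angle(analytic)) + phase_offset, 2 * np.pi)
    total_cycles = (np.unwrap(np.angle(analytic))[-1]
                    - np.unwrap(np.angle(analytic))[0]) / (2 * np.pi)
    if total_cycles < 10:
        raise ValueError(f"only {total_cycles:.1f} complete cycles; need >= 10")

    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    rate = np.array([sim.rate_raw[keep][idx == b].mean() for b in range(n_bins)])
    mvb = np.array([mv[idx == b].mean() for b in range(n_bins)])

    v_std = np.full(n_bins, np.nan)
    v_edges = v_hist = None
    if sim.snapshots is not None and len(sim.snapshots):
        skeep = sim.snapshot_t >= sim.t[0] + discard_ms
        st = sim.snapshot_t[skeep]
        sv = sim.snapshots[skeep]
        sphase = np.interp(st, t, phase)
        sidx = np.clip(np.digitize(sphase, edges) - 1, 0, n_bins - 1)
        lo, hi = sv.min(), sv.max()
        v_edges = np.linspace(lo, hi, 101)
        v_hist = np.zeros((n_bins, 100))
        for b in range(n_bins):
            sel = sv[sidx == b]
            if sel.size:
                v_std[b] = sel.std()
                v_hist[b], _ = np.histogram(sel.ravel(), bins=v_edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PopulationCycleAverage(
        phase=centers, rate=rate, mean_voltage=mvb, voltage_std=v_std,
        voltage_edges=v_edges, voltage_hist=v_hist,
        n_cycles=int(total_cycles))


__all__ = ["SimResult", "simulate", "population_rate", "smooth_rate",
           "PopulationCycleAverage", "average_cycle"]
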