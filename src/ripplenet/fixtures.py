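"""Small deterministic fixtures for tests and demos.

Everything here is generated programmatically (no stored data): short
small-N spiking runs, synthetic chirps and flat traces for exercising
the frequency estimators.
"""

from __future__ import annotations

import numpy as np

from .drive import constant_drive, make_spw_drive
from .network import SimResult, simulate
from .params import DimensionlessParams


def make_fixture(kind: str, seed: int = 0):
    """Return a named fixture.

    Kinds
    -----
    ``chirp``
        (t_ms, rate) trace whose oscillation frequency sweeps linearly
        250 -> 150 Hz over 100 ms after a 200 ms flat baseline.
    ``flat``
        constant-rate trace with weak white noise.
    ``sparse-synchrony``
        N = 100 spiking run at constant drive in the sparse-synchrony
        regime (2 s, dt = 0.02 ms).
    ``spw-small``
        N = 100 spiking run under the default double-ramp stimulus.
    """
    rng = np.random.default_rng(seed)
    dt = 0.05  # ms, trace fixtures
    if kind == "chirp":
        t_base = np.arange(0, 200.0, dt)
        t_ev = np.arange(0, 100.0, dt)
        f0, f1 = 250.0, 150.0
        phase = 2 * np.pi * (f0 * t_ev + 0.5 * (f1 - f0) / 100.0 * t_ev ** 2) / 1000.0
        base = 20.0 + rng.normal(0, 1.0, t_base.size)
        ev = 20.0 + 400.0 * np.clip(np.sin(phase), 0, None) ** 2 \
            + rng.normal(0, 1.0, t_ev.size)
        rate = np.concatenate([base, ev])
        t = np.arange(rate.size) * dt
        return t, rate
    if kind == "flat":
        t = np.arange(0, 300.0, dt)
        return t, 50.0 + rng.normal(0, 0.5, t.size)
    if kind == "sparse-synchrony":
        p = DimensionlessParams(N=100)
        return simulate(p, 4.2, duration=2000.0, dt=0.02, seed=seed)
    if kind == "spw-small":
        p = DimensionlessParams(N=100)
        drv = make_spw_drive(0.74, 8.9, 0.4, t_baseline=200.0, t_plateau=20.0,
                             t_tail=30.0)
        return simulate(p, drv, dt=0.02, seed=seed)
    raise KeyError(f"unknown fixture kind {kind!r}")


__all__ = ["make_fixture"]
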