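"""External-drive time courses.

A :class:`DriveProfile` is an ordered list of contiguous linear
segments ``(t_start, t_end, value_start, value_end)``.  The canonical
sharp-wave (SPW) stimulus is a symmetric piecewise-linear double ramp:
a baseline hold, a rise at slope ``+m`` to a plateau, a plateau hold,
and a fall at ``-m`` back to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class DriveProfile:
    """Piecewise-linear drive, evaluable at any time inside its span.

    ``units`` records whether values are dimensionless drive (``I_E``)
    or physical current in nA (``nA``).
    """

    segments: tuple[tuple[float, float, float, float], ...]
    units: str = "I_E"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("profile needs at least one segment")
        prev_end = None
        for (t0, t1, _, _) in self.segments:
            if t1 <= t0:
                raise ValueError("segment must have positive duration")
            if prev_end is not None and abs(t0 - prev_end) > 1e-9:
                raise ValueError("segments must be contiguous")
            prev_end = t1

    @property
    def t_start(self) -> float:
        return self.segments[0][0]

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    def __call__(self, t):
        return eval_drive(self, t)

    def sample(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate on a regular grid with step ``dt`` over the span."""
        t = np.arange(self.t_start, self.t_end + 0.5 * dt, dt)
        t[-1] = min(t[-1], self.t_end)
        return t, eval_drive(self, t)

    def to_text(self, path) -> None:
        """Serialize segment knots as two-column text (t_ms, value)."""
        knots = [(s[0], s[2]) for s in self.segments] + [(self.segments[-1][1], self.segments[-1][3])]
        np.savetxt(path, np.asarray(knots), header=f"t_ms value ({self.units})")


def constant_drive(value: float, duration: float, units: str = "I_E",
                   t_start: float = 0.0) -> DriveProfile:
    """A constant drive held for ``duration`` ms."""
    return DriveProfile(((t_start, t_start + duration, value, value),), units)


def make_spw_drive(baseline: float, plateau: float, slope_m: float,
                   t_baseline: float = 200.0, t_plateau: float = 20.0,
                   t_tail: float = 0.0, units: str = "I_E") -> DriveProfile:
    """Symmetric double-ramp sharp-wave stimulus.

    Baseline hold of ``t_baseline`` ms, linear rise at ``+slope_m`` per
    ms up to ``plateau``, plateau hold of ``t_plateau`` ms, linear fall
    at ``-slope_m`` back to ``baseline``, optionally followed by a
    baseline tail of ``t_tail`` ms.  The profile is time-symmetric
    about the plateau midpoint.
    """
    if slope_m <= 0:
        raise ValueError("slope_m must be positive")
    if plateau <= baseline:
        raise ValueError("plateau must exceed baseline")
    ramp = (plateau - baseline) / slope_m
    t1 = t_baseline
    t2 = t1 + ramp
    t3 = t2 + t_plateau
    t4 = t3 + ramp
    segs = [
        (0.0, t1, baseline, baseline),
        (t1, t2, baseline, plateau),
        (t2, t3, plateau, plateau),
        (t3, t4, plateau, baseline),
    ]
    if t_tail > 0:
        segs.append((t4, t4 + t_tail, baseline, baseline))
    return DriveProfile(tuple(segs), units)


def eval_drive(d: DriveProfile, t):
    """Piecewise-linear interpolation, exact at the knots."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < d.t_start - 1e-9) or np.any(t_arr > d.t_end + 1e-9):
        raise ValueError(
            f"time outside profile span [{d.t_start}, {d.t_end}] ms")
    out = np.empty_like(t_arr)
    out.fill(np.nan)
    for (t0, t1, v0, v1) in d.segments:
        mask = (t_arr >= t0 - 1e-9) & (t_arr <= t1 + 1e-9)
        if np.any(mask):
            w = np.clip((t_arr[mask] - t0) / (t1 - t0), 0.0, 1.0)
            out[mask] = v0 + w * (v1 - v0)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def spw_times(d: DriveProfile) -> tuple[float, float, float, float]:
    """Knot times (t1, t2, t3, t4) of a 4/5-segment SPW profile:
    baseline end, plateau start, plateau end, return to baseline."""
    if len(d.segments) < 4:
        raise ValueError("not an SPW profile")
    return (d.segments[0][1], d.segments[1][1], d.segments[2][1], d.segments[3][1])


__all__ = ["DriveProfile", "constant_drive", "make_spw_drive", "eval_drive",
           "spw_times"]
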