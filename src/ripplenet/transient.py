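"""Transient cycle theory for linearly changing drive and the IFA slope.

Each oscillation cycle under a drive ``I_E(t) = I_hat + m (t - t_off)``
is described by the map

    (I_hat, mu_min, m)  ->  (f_inst, t_off, mu_max, mu_reset, mu_min')

anchored at the end of the population spike (where the drive equals
``I_hat``).  mu_max solves a transcendental end-of-spike condition
seeded at the constant-drive value; t_off comes from a Lambert-W
closed form; the end-of-cycle potential mu_min' integrates the delayed
inhibitory feedback along the transient upstroke trajectory.

Chaining consecutive cycles self-consistently over a symmetric double
ramp (rise at +m to a plateau, 20 ms plateau, fall at -m) produces the
theoretical instantaneous-frequency trace whose pooled regression
slope is the intra-ripple frequency accommodation (IFA) slope chi_IFA.
The hysteresis of mu_min -- each cycle starts at the minimum set by
the previous cycle's drive -- makes rising-ramp cycles fast and
falling-ramp cycles slow, hence chi_IFA < 0 for symmetric drive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import lambertw

from .params import as_dimensionless
from . import theory
from .theory import NoOscillation


@dataclass(frozen=True)
class LinearCycleInput:
    """One transient cycle: reference drive at t_off, initial mean
    potential, and drive slope (per ms)."""

    I_hat: float
    mu_min: float
    m: float


@dataclass(frozen=True)
class TransientCycle:
    """Solved transient cycle (times in ms, f in Hz)."""

    I_hat: float
    mu_min: float
    m: float
    mu_max: float
    mu_reset: float
    s: float
    t_off: float
    T: float
    f_inst: float
    f_unit: float
    mu_min_next: float
    perturbative: bool = False       # mu_max fell back to the O(m) form
    has_asymptotic_ref: bool = True  # I_hat inside the constant-drive range


@dataclass
class CycleChain:
    """Chained cycles over one ramp, with absolute timestamps.

    ``t_start`` of each cycle is such that the rising chain ends at
    t = 0 (plateau onset) and the falling chain starts at the plateau
    end.
    """

    cycles: list
    t_starts: list
    direction: str               # "rising" | "falling"
    plateau: float
    slope: float

    def points(self, stamp: str = "mid"):
        """(t, f_inst) pairs; ``stamp`` places each frequency at the
        cycle midpoint (default), start, end, or population-spike time."""
        out = []
        for t0, c in zip(self.t_starts, self.cycles):
            t = {"mid": t0 + c.T / 2, "start": t0, "end": t0 + c.T,
                 "toff": t0 + c.t_off}[stamp]
            out.append((t, c.f_inst))
        return out


def mu_max_linear(inp: LinearCycleInput, params):
    """Transcendental cycle maximum under linear drive.

    Solved numerically in a bracket around the constant-drive value;
    falls back to the first-order-in-m perturbative form when the
    bracket contains no root.  Returns (mu_max, perturbative_flag).
    """
    p = as_dimensionless(params)
    mm0 = theory.mu_max(inp.I_hat, p)
    if inp.m == 0:
        return mm0, False
    e1 = math.exp(p.delta / p.tau_m)
    sq = math.sqrt(2.0 * math.pi * p.D)

    def F(mu: float) -> float:
        hist = (inp.I_hat + (mu - inp.I_hat) * e1
                + inp.m * (p.tau_m * e1 - (p.delta + p.tau_m)))
        dens = math.exp(-(p.V_T - hist) ** 2 / (2.0 * p.D)) / sq
        drive_minus_mu = (inp.I_hat - mu) * e1 - inp.m * p.tau_m * (e1 - 1.0)
        return inp.I_hat - mu - p.K * drive_minus_mu * dens

    for half in (0.05, 0.1, 0.2, 0.4):
        lo, hi = mm0 - half, mm0 + half
        if F(lo) * F(hi) < 0:
            return brentq(F, lo, hi), False
    return mm0 + inp.m * mu_max_slope(inp.I_hat, p), True


def mu_max_slope(I_hat: float, params, dm: float = 1e-6) -> float:
    """First-order coefficient d(mu_max)/dm at m = 0 (implicit-function
    derivative of the transcendental end-of-spike condition; negative
    for default-like parameters, so rising drive slightly lowers the
    cycle maximum)."""
    p = as_dimensionless(params)
    hi, _ = mu_max_linear(LinearCycleInput(I_hat, 0.0, dm), p)
    lo, _ = mu_max_linear(LinearCycleInput(I_hat, 0.0, -dm), p)
    return (hi - lo) / (2.0 * dm)


def t_off_linear(inp: LinearCycleInput, mu_max_val: float, params):
    """Upstroke duration under linear drive (Lambert-W closed form).

    The physical root is the smallest positive one among the real
    branches: the principal branch W0 for rising drive, W-1 for
    falling drive (each is the unique branch continuous with the
    m -> 0 limit).  Returns None where no transient solution exists.
    """
    p = as_dimensionless(params)
    if inp.m == 0:
        return theory.t_off(inp.mu_min, mu_max_val, inp.I_hat, p)
    if mu_max_val <= inp.mu_min:
        return 0.0 if mu_max_val == inp.mu_min else None
    mt = inp.m * p.tau_m
    a = inp.I_hat - mt
    # closed form: t_off = -tau W(z) + (a - mu_min)/m with
    # z = (a - mu_max)/(m tau) exp(-1 + (I_hat - mu_min)/(m tau)).
    # For small |m| the two terms cancel catastrophically (and the exp
    # overflows), so the same equation is solved directly:
    #   g(t) = (mu_min - a + m t) e^{-t/tau} - (mu_max - a) = 0
    # taking the first positive root (the branch continuous with m -> 0).
    use_lambert = abs(inp.m) * p.tau_m > 0.5 and \
        abs((inp.I_hat - inp.mu_min) / mt) < 500.0
    if use_lambert:
        arg = (a - mu_max_val) / mt * math.exp(-1.0 + (inp.I_hat - inp.mu_min) / mt)
        if arg < -math.exp(-1.0) - 1e-12:
            return None
        arg = max(arg, -math.exp(-1.0))
        roots = []
        for branch in (0, -1):
            if branch == -1 and arg >= 0:
                continue
            w = lambertw(arg, branch)
            if abs(w.imag) > 1e-10:
                continue
            t = -p.tau_m * float(w.real) + (a - inp.mu_min) / inp.m
            if t > 0:
                roots.append(t)
        return min(roots) if roots else None

    def g(t: float) -> float:
        return (inp.mu_min - a + inp.m * t) * math.exp(-t / p.tau_m) \
            - (mu_max_val - a)

    t_scan = np.linspace(0.0, 60.0, 2401)
    vals = np.array([g(t) for t in t_scan])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if sign_change.size == 0:
        return None
    i = sign_change[0]
    root = brentq(g, t_scan[i], t_scan[i + 1], xtol=1e-12)
    return root if root > 0 else None


def _mu_min_next(inp: LinearCycleInput, mu_max_val: float, mu_reset_val: float,
                 params) -> float:
    """End-of-cycle potential: closed-form constant-drive part plus the
    exact linear-drive correction.

    The correction integrates the total current over the downstroke
    with the Gaussian factors evaluated on the transient upstroke
    trajectory, minus the same quadrature at m = 0; this vanishes
    identically at m = 0, so the map reduces exactly to the
    constant-drive closed form there.
    """
    p = as_dimensionless(params)
    sq = math.sqrt(2.0 * math.pi * p.D)
    IEh, mm = inp.I_hat, mu_max_val

    def quadpart(m: float) -> float:
        def hist(x: float) -> float:  # mu(t_off - x) during the upstroke
            ex = math.exp(x / p.tau_m)
            return IEh + (mm - IEh) * ex + m * (p.tau_m * ex - (x + p.tau_m))

        def dens(x: float) -> float:
            return math.exp(-(p.V_T - hist(x)) ** 2 / (2.0 * p.D)) / sq

        def current(t: float) -> float:
            e_a = math.exp((p.delta - t) / p.tau_m)
            e_b = math.exp((2.0 * p.delta - t) / p.tau_m)
            b1 = (IEh - mm) * e_a - m * p.tau_m * (e_a - 1.0)
            b2 = (IEh - mm) * e_b - m * p.tau_m * (e_b - 1.0)
            p1 = dens(p.delta - t)
            p2 = dens(2.0 * p.delta - t)
            return IEh + m * t - p.K * p1 * b1 + p.K * p.K * p1 * p2 * b2

        val, _ = quad(lambda t: current(t) * math.exp(-(p.delta - t) / p.tau_m),
                      0.0, p.delta, limit=200)
        return val / p.tau_m

    decay = math.exp(-p.delta / p.tau_m)
    stat = (mu_reset_val * decay + IEh * (1.0 - decay)
            - theory._inhibition_bracket(IEh, mm, p))
    return stat + quadpart(inp.m) - quadpart(0.0)


def cycle_map(inp: LinearCycleInput, params) -> TransientCycle | None:
    """Full transient-cycle map; None where no cycle solution exists."""
    p = as_dimensionless(params)
    try:
        mm, pert = mu_max_linear(inp, p)
    except NoOscillation:
        return None
    toff = t_off_linear(inp, mm, p)
    if toff is None or toff <= 0:
        return None
    s = theory.saturation_of_mu_max(mm, p)
    mr = theory.mu_reset(mm, s, p)
    mn_next = _mu_min_next(inp, mm, mr, p)
    T = toff + p.delta
    f = 1000.0 / T
    lo = theory.oscillation_drive_threshold(p)
    return TransientCycle(
        I_hat=inp.I_hat, mu_min=inp.mu_min, m=inp.m, mu_max=mm, mu_reset=mr,
        s=s, t_off=toff, T=T, f_inst=f, f_unit=s * f, mu_min_next=mn_next,
        perturbative=pert, has_asymptotic_ref=inp.I_hat > lo)


def _subthreshold_bound(p) -> float:
    return p.V_T - 3.0 * math.sqrt(p.D)


def _solve_cycle(drive_start: float, mu_min: float, m: float, p,
                 tol: float = 1e-6, max_iter: int = 100):
    """Fixed-point solve for the reference drive of a cycle whose start
    drive is known: I_hat = drive_start + m * t_off(I_hat)."""
    I_hat = drive_start
    cyc = None
    for _ in range(max_iter):
        cyc = cycle_map(LinearCycleInput(I_hat, mu_min, m), p)
        if cyc is None:
            return None
        I_new = drive_start + m * cyc.t_off
        if abs(I_new - I_hat) < tol:
            return cycle_map(LinearCycleInput(I_new, mu_min, m), p)
        I_hat = I_new
    raise RuntimeError("cycle fixed-point iteration did not converge")


def _chain_rising_from(I_hat1: float, m: float, plateau: float, p,
                       max_cycles: int = 80):
    """Forward chain from a first cycle at the subthreshold-validity
    boundary; returns None when any cycle start is invalid."""
    bound = _subthreshold_bound(p)
    cycles = []
    mu_min = bound
    I_hat = I_hat1
    for _ in range(max_cycles):
        if mu_min > bound + 1e-9:
            return None
        cyc = cycle_map(LinearCycleInput(I_hat, mu_min, m), p)
        if cyc is None:
            return None
        cycles.append(cyc)
        end_drive = cyc.I_hat + m * p.delta
        if end_drive >= plateau - 1e-9:
            return cycles
        mu_min = cyc.mu_min_next
        try:
            nxt = _solve_cycle(end_drive, mu_min, m, p)
        except RuntimeError:
            return None
        if nxt is None:
            return None
        I_hat = nxt.I_hat
    return cycles


def chain_rising(m: float, plateau: float, baseline: float, params,
                 scan_step: float = 0.02) -> CycleChain:
    """Rising-ramp chain anchored so that the drive at the end of the
    last cycle equals the plateau level.

    The first cycle starts at the subthreshold-validity boundary
    ``mu_min = V_T - 3 sqrt(D)``; among anchored chains the longest
    branch is selected (the ripple starts as early as the theory
    permits) and the anchor is enforced by bisection on the first
    cycle's reference drive at the branch boundary.
    """
    p = as_dimensionless(params)
    if m <= 0:
        raise ValueError("rising chain needs m > 0")

    def probe(I1: float):
        ch = _chain_rising_from(I1, m, plateau, p)
        if ch is None:
            return None
        if ch[0].I_hat - m * ch[0].t_off < baseline - 1e-9:
            return None
        return ch

    grid = np.arange(max(baseline, 0.8), plateau, scan_step)
    lens = []
    for I1 in grid:
        ch = probe(float(I1))
        lens.append(None if ch is None else len(ch))
    # branch boundaries: chain length drops by one as I1 grows past the
    # point where the last cycle exactly lands on the plateau
    cands = [(lens[i + 1], grid[i], grid[i + 1])
             for i in range(len(grid) - 1)
             if lens[i] is not None and lens[i + 1] is not None
             and lens[i] == lens[i + 1] + 1]
    if not cands:
        raise NoOscillation("no anchored rising chain found")
    n, lo, hi = max(cands)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        ch = probe(mid)
        if ch is not None and len(ch) == n:
            hi = mid
        else:
            lo = mid
    cycles = probe(hi)
    total = sum(c.T for c in cycles)
    t_starts = list(np.cumsum([0.0] + [c.T for c in cycles[:-1]]) - total)
    return CycleChain(cycles=cycles, t_starts=t_starts, direction="rising",
                      plateau=plateau, slope=m)


def chain_falling(m: float, plateau: float, baseline: float, params,
                  t_start: float = 0.0) -> CycleChain:
    """Falling-ramp chain started from the asymptotic plateau state.

    Cycles are added while their start potential is validly
    subthreshold and the drive remains above baseline; trailing cycles
    whose reference drive falls below the constant-drive range are
    kept but flagged (no asymptotic reference).
    """
    p = as_dimensionless(params)
    if m >= 0:
        raise ValueError("falling chain needs m < 0")
    bound = _subthreshold_bound(p)
    mu_min_val = theory.mu_min(plateau, p, with_reset=True)
    drive_start = plateau
    cycles, t_starts = [], []
    t = t_start
    for _ in range(80):
        if mu_min_val > bound + 1e-9 or drive_start < baseline - 1e-9:
            break
        cyc = _solve_cycle(drive_start, mu_min_val, m, p)
        if cyc is None:
            break
        cycles.append(cyc)
        t_starts.append(t)
        t += cyc.T
        mu_min_val = cyc.mu_min_next
        drive_start = cyc.I_hat + m * p.delta
    return CycleChain(cycles=cycles, t_starts=t_starts, direction="falling",
                      plateau=plateau, slope=m)


@dataclass(frozen=True)
class TheoryIfa:
    """Theory-side IFA result for one double-ramp stimulus."""

    chi_ifa: float
    intercept: float
    points: tuple
    rising: CycleChain = field(repr=False, default=None)
    falling: CycleChain = field(repr=False, default=None)


def theory_ifa(m: float, params, plateau: float = 8.9,
               plateau_len: float = 20.0, baseline: float | None = None,
               stamp: str = "mid") -> TheoryIfa:
    """Chain both ramps of the symmetric double-ramp stimulus and
    regress instantaneous frequency on time (plateau cycles excluded,
    falling chain shifted by the plateau length)."""
    p = as_dimensionless(params)
    if baseline is None:
        baseline = 0.74  # half the spiking network's critical drive (defaults)
    rise = chain_rising(abs(m), plateau, baseline, p)
    fall = chain_falling(-abs(m), plateau, baseline, p, t_start=plateau_len)
    pts = rise.points(stamp) + fall.points(stamp)
    t = np.array([q[0] for q in pts])
    f = np.array([q[1] for q in pts])
    slope = float(np.cov(f, t, ddof=1)[0, 1] / np.var(t, ddof=1))
    intercept = float(f.mean() - slope * t.mean())
    return TheoryIfa(chi_ifa=slope, intercept=intercept, points=tuple(pts),
                     rising=rise, falling=fall)


def theory_sim_error(chain_points, sim_series, window: float = 1.5) -> float:
    """Mean relative deviation of theoretical instantaneous frequencies
    from simulated ones averaged in a +-``window`` ms neighbourhood.

    ``chain_points``: (t, f) pairs on the simulation clock;
    ``sim_series``: iterable of InstFreqSeries (pooled)."""
    ts, fs = [], []
    for s in sim_series:
        ts.append(np.asarray(s.t)[np.asarray(s.valid, bool)])
        fs.append(np.asarray(s.f)[np.asarray(s.valid, bool)])
    t_sim = np.concatenate(ts)
    f_sim = np.concatenate(fs)
    errs = []
    for (t, f) in chain_points:
        sel = np.abs(t_sim - t) <= window
        if np.any(sel):
            ref = f_sim[sel].mean()
            errs.append(abs(f - ref) / ref)
    if not errs:
        raise ValueError("no overlap between theory cycles and simulated points")
    return float(np.mean(errs))


__all__ = ["LinearCycleInput", "TransientCycle", "CycleChain",
           "mu_max_linear", "t_off_linear", "cycle_map", "chain_rising",
           "chain_falling", "TheoryIfa", "theory_ifa", "theory_sim_error"]
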