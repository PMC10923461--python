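"""Closed-form constant-drive theory of the oscillation cycle.

For strong constant drive the Gaussian-drift mean field oscillates
between a local minimum mu_min and maximum mu_max of the mean membrane
potential.  The cycle splits into an upstroke of duration t_off (rise
from mu_min to mu_max under the external drive alone) and a downstroke
of exactly one synaptic delay Delta (the delayed inhibition generated
by the population spike).  All cycle quantities follow in closed form:

* mu_max from the self-consistent end-of-spike condition (independent
  of mu_min),
* the saturation s as the suprathreshold Gaussian mass at mu_max,
* the population reset mu_reset = mu_max - (V_T - V_R) s,
* mu_min by integrating the delayed inhibitory feedback over the
  downstroke (erf expressions, with mu_max or mu_reset as the initial
  condition),
* t_off = tau_m ln[(I_E - mu_min)/(I_E - mu_max)] and the network
  frequency f_net = 1/(t_off + Delta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .params import DimensionlessParams, as_dimensionless


class NoOscillation(ValueError):
    """Raised when the closed-form cycle does not exist at this drive."""


@dataclass(frozen=True)
class CycleSolution:
    """One asymptotic oscillation cycle at constant drive."""

    I_E: float
    mu_min: float
    mu_max: float
    mu_reset: float
    t_off: float       # ms
    T: float           # ms
    f_net: float       # Hz
    s: float           # saturation = f_unit / f_net
    f_unit: float      # Hz
    with_reset: bool


@dataclass(frozen=True)
class ApplicabilityRange:
    """Drive range on which the Gaussian-drift cycle theory applies."""

    IE_min: float
    IE_max: float
    lower_constraint: str = "subthreshold"   # mu_min + 3 sqrt(D) <= V_T
    upper_constraint: str = "single-spike"   # I_E <= I_E^full


@dataclass(frozen=True)
class PerformanceScores:
    """Theory-vs-simulation scores on the shared drive grid."""

    chi_err: float
    chi_appl: float
    chi_p: float


def _log_term(p: DimensionlessParams) -> float:
    arg = p.K / math.sqrt(2.0 * math.pi * p.D) * math.exp(p.delta / p.tau_m)
    if arg < 1.0:
        raise NoOscillation(
            f"coupling too weak: K={p.K} < sqrt(2 pi D) e^(-Delta/tau_m)")
    return math.log(arg)


def oscillation_drive_threshold(params) -> float:
    """Analytic lower bound on the drive for oscillations: below
    ``V_T - sqrt(2 D ln[K e^(Delta/tau) / sqrt(2 pi D)])`` the mean
    settles into the zero-rate fixed point."""
    p = as_dimensionless(params)
    return p.V_T - math.sqrt(2.0 * p.D * _log_term(p))


def mu_max(I_E: float, params) -> float:
    """Cycle maximum of the mean membrane potential (independent of
    mu_min)."""
    p = as_dimensionless(params)
    root = math.sqrt(2.0 * p.D * _log_term(p))
    bound = p.V_T - root
    if I_E < bound:
        raise NoOscillation(
            f"drive I_E={I_E:.4g} below the oscillation threshold {bound:.4g}")
    return I_E - math.exp(-p.delta / p.tau_m) * (I_E - p.V_T + root)


def saturation_of_mu_max(mu_max_val: float, params) -> float:
    """Suprathreshold Gaussian mass at the end of the population spike:
    s = (1 - erf((V_T - mu_max)/sqrt(2 D)))/2."""
    p = as_dimensionless(params)
    return 0.5 * (1.0 - erf((p.V_T - mu_max_val) / math.sqrt(2.0 * p.D)))


def mu_reset(mu_max_val: float, s: float, params) -> float:
    """Population reset: the Gaussian mean after shifting the spiked
    fraction s down by the threshold-to-reset distance."""
    p = as_dimensionless(params)
    return mu_max_val - (p.V_T - p.V_R) * s


def _inhibition_bracket(I_E: float, mu_max_val: float, p: DimensionlessParams) -> float:
    """The closed-form inhibitory-feedback term shared by the no-reset
    and with-reset expressions for mu_min."""
    e1 = math.exp(p.delta / p.tau_m)
    e2 = math.exp(2.0 * p.delta / p.tau_m)
    sq2d = math.sqrt(2.0 * p.D)

    def phi(t: float) -> float:
        return (p.V_T - mu_max_val + (I_E - mu_max_val) * (p.delta - t) / p.tau_m) / sq2d

    def psi(t: float) -> float:
        num = (-(I_E - mu_max_val) * (e2 + 1.0) * (p.tau_m + p.delta - t)
               + p.tau_m * (I_E - p.V_T) * (e1 + 1.0))
        return num / (math.sqrt(2.0 * p.D * (e2 + 1.0)) * p.tau_m)

    c = (p.V_T - I_E) ** 2 * (1.0 - e1) ** 2 / (e2 + 1.0)
    first = erf(phi(0.0)) - erf(phi(p.delta))
    second = (p.K / math.sqrt(2.0 * math.pi * p.D) * math.exp(-c / (2.0 * p.D))
              * e1 / math.sqrt(e2 + 1.0) * (erf(psi(p.delta)) - erf(psi(0.0))))
    return 0.5 * p.K * (first - second)


def mu_min(I_E: float, params, with_reset: bool = True) -> float:
    """Mean membrane potential at the end of the cycle (t_off + Delta).

    With the population reset the downstroke starts from mu_reset
    instead of mu_max, lowering mu_min.
    """
    p = as_dimensionless(params)
    mm = mu_max(I_E, p)
    if with_reset:
        mu0 = mu_reset(mm, saturation_of_mu_max(mm, p), p)
    else:
        mu0 = mm
    decay = math.exp(-p.delta / p.tau_m)
    return mu0 * decay + I_E * (1.0 - decay) - _inhibition_bracket(I_E, mm, p)


def t_off(mu_min_val: float, mu_max_val: float, I_E: float, params) -> float:
    """Upstroke duration: exponential relaxation from mu_min to mu_max
    towards the external drive."""
    p = as_dimensionless(params)
    if not (I_E > mu_max_val >= mu_min_val):
        raise ValueError("need I_E > mu_max >= mu_min for a rise time")
    return p.tau_m * math.log((I_E - mu_min_val) / (I_E - mu_max_val))


def constant_drive_solution(I_E: float, params,
                            with_reset: bool = True) -> CycleSolution:
    """Assemble the full closed-form cycle at constant drive."""
    p = as_dimensionless(params)
    mm = mu_max(I_E, p)
    s = saturation_of_mu_max(mm, p)
    mr = mu_reset(mm, s, p)
    mn = mu_min(I_E, p, with_reset=with_reset)
    toff = t_off(mn, mm, I_E, p)
    T = toff + p.delta
    f_net = 1000.0 / T
    return CycleSolution(I_E=I_E, mu_min=mn, mu_max=mm, mu_reset=mr,
                         t_off=toff, T=T, f_net=f_net, s=s,
                         f_unit=s * f_net, with_reset=with_reset)


def full_synchrony_drive(params) -> float:
    """Closed-form drive at which (approximate) full synchrony is
    reached: the drive for which mu_max - 3 sqrt(D) = V_T (s = 0.9987)."""
    p = as_dimensionless(params)
    e = math.exp(-p.delta / p.tau_m)
    return p.V_T + math.sqrt(p.D) * (3.0 + e * math.sqrt(2.0 * _log_term(p))) / (1.0 - e)


def applicability_range(params, tol: float = 1e-4) -> ApplicabilityRange:
    """Drive range [I_E^min, I_E^max] of the cycle theory.

    The lower end requires the cycle minimum to sit at least 3 sqrt(D)
    below threshold (bulk of the density subthreshold between spikes);
    the upper end is the point of full synchrony unless the
    subthreshold condition re-binds at high drive (high-noise /
    weak-coupling corner).
    """
    p = as_dimensionless(params)
    ie_full = full_synchrony_drive(p)
    lo = oscillation_drive_threshold(p) + 1e-9

    def slack(I_E: float) -> float:
        return p.V_T - (mu_min(I_E, p, with_reset=True) + 3.0 * math.sqrt(p.D))

    grid = np.linspace(lo, ie_full, 200)
    sl = np.array([slack(g) for g in grid])
    if np.all(sl < 0):
        raise NoOscillation("empty applicability range for these parameters")
    ok = np.flatnonzero(sl >= 0)
    if ok[0] == 0:
        ie_min = lo
    else:
        ie_min = brentq(slack, grid[ok[0] - 1], grid[ok[0]], xtol=tol)
    if ok[-1] == grid.size - 1:
        ie_max, upper = ie_full, "single-spike"
    else:
        ie_max = brentq(slack, grid[ok[-1]], grid[ok[-1] + 1], xtol=tol)
        upper = "subthreshold"
    return ApplicabilityRange(IE_min=float(ie_min), IE_max=float(ie_max),
                              upper_constraint=upper)


def performance_scores(drive_grid, f_theory, f_sim, IE_crit_sim: float,
                       IE_full_sim: float, IE_min: float,
                       IE_max: float) -> PerformanceScores:
    """Theory-vs-simulation performance on the common drive grid.

    ``chi_err`` is the mean relative frequency error on the grid,
    ``chi_appl`` the covered fraction of the relevant drive range
    (Hopf point to simulated full synchrony), ``chi_p`` their product
    ``chi_appl (1 - chi_err)``.
    """
    drive_grid = np.asarray(drive_grid, dtype=float)
    f_theory = np.asarray(f_theory, dtype=float)
    f_sim = np.asarray(f_sim, dtype=float)
    if drive_grid.size == 0:
        raise ValueError("empty drive grid")
    chi_err = float(np.mean(np.abs(f_sim - f_theory) / f_sim))
    chi_appl = (min(IE_max, IE_full_sim) - IE_min) / (IE_full_sim - IE_crit_sim)
    chi_appl = float(np.clip(chi_appl, 0.0, 1.0))
    return PerformanceScores(chi_err=chi_err, chi_appl=chi_appl,
                             chi_p=chi_appl * (1.0 - chi_err))


def frequency_curve(params, drives, with_reset: bool = True):
    """Vector evaluation of f_net over a drive array (NaN where the
    cycle does not exist)."""
    out = np.full(len(drives), np.nan)
    for i, ie in enumerate(drives):
        try:
            out[i] = constant_drive_solution(float(ie), params, with_reset).f_net
        except (NoOscillation, ValueError):
            pass
    return out


__all__ = ["CycleSolution", "ApplicabilityRange", "PerformanceScores",
           "NoOscillation", "oscillation_drive_threshold", "mu_max",
           "saturation_of_mu_max", "mu_reset", "mu_min", "t_off",
           "constant_drive_solution", "full_synchrony_drive",
           "applicability_range", "performance_scores", "frequency_curve"]
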