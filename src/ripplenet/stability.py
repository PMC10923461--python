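"""Stationary state and Hopf bifurcation of the mean-field network.

The asynchronous stationary state solves the self-consistency

    I_0 = I_E - K tau_m r_0,      r_0 = f_LIF(I_0),

with f_LIF the white-noise LIF rate (Siegert integral).  Its linear
stability against a weak periodic rate perturbation at angular
frequency omega is governed by the exact LIF susceptibility G(omega)
(complex-order parabolic cylinder functions); the stationary state
loses stability where both

    1 = K tau_m |G|          (amplitude condition)
    0 = pi + arg(G) - omega Delta   (phase condition)

hold.  Solving the pair yields the critical drive of the supercritical
Hopf bifurcation and the network/unit frequencies at onset.

All internal computations use time in units of tau_m and dimensionless
voltage; results are reported in ms/Hz (and nA where requested).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import mpmath as mp
import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import erfcx

from .params import as_dimensionless, drive_to_physical


@dataclass(frozen=True)
class StationaryState:
    """Self-consistent asynchronous state at external drive I_E."""

    I_E: float
    I0: float        # total drive (external minus feedback)
    r0: float        # stationary rate, units 1/tau_m
    r0_hz: float     # same in Hz


@dataclass(frozen=True)
class HopfPoint:
    """Oscillation onset of the mean-field network."""

    IE_crit: float       # dimensionless external drive
    I_ext_crit_nA: float # physical drive (default capacitance/voltage scale)
    f_net_hz: float      # network frequency at onset
    f_unit_hz: float     # stationary unit rate at onset
    omega: float         # dimensionless angular frequency (units 1/tau_m)

    @property
    def saturation(self) -> float:
        return self.f_unit_hz / self.f_net_hz


def lif_rate(I: float, params) -> float:
    """White-noise LIF firing rate (units of 1/tau_m).

    ``1/r = sqrt(pi) Int_{(I-V_T)/sqrt(2D)}^{(I-V_R)/sqrt(2D)} e^{x^2}
    erfc(x) dx + tau_ref/tau_m`` evaluated with the scaled complementary
    error function for stability.
    """
    p = as_dimensionless(params)
    lo = (I - p.V_T) / math.sqrt(2.0 * p.D)
    hi = (I - p.V_R) / math.sqrt(2.0 * p.D)
    if hi < -25.0:
        # so deeply subthreshold that e^{x^2} erfc(x) overflows double
        # precision; the rate is numerically zero
        return 0.0
    val, err = quad(erfcx, lo, hi, limit=200)
    if not np.isfinite(val) or (val > 0 and err / max(val, 1e-300) > 1e-5):
        raise RuntimeError("f-I quadrature did not converge")
    denom = math.sqrt(math.pi) * val + p.tau_ref / p.tau_m
    return 1.0 / denom


def lif_rate_hz(I: float, params) -> float:
    p = as_dimensionless(params)
    return lif_rate(I, p) * 1000.0 / p.tau_m


def stationary_state(I_E: float, params, tol: float = 1e-10) -> StationaryState:
    """Solve the stationary self-consistency by bisection on I_0
    (f_LIF is increasing, the feedback map is a contraction in I_0)."""
    p = as_dimensionless(params)

    def g(I0: float) -> float:
        return I0 - (I_E - p.K * lif_rate(I0, p))

    hi = I_E                      # K r >= 0
    lo = I_E - p.K * lif_rate(I_E, p) - 1.0
    while g(lo) > 0:
        lo -= 1.0
    I0 = brentq(g, lo, hi, xtol=tol)
    r0 = lif_rate(I0, p)
    return StationaryState(I_E=I_E, I0=I0, r0=r0, r0_hz=r0 * 1000.0 / p.tau_m)


def susceptibility(omega: float, state: StationaryState, params) -> complex:
    """Exact LIF rate response to weak periodic drive modulation.

    ``omega`` is the angular frequency in units of 1/tau_m.  Evaluated
    with arbitrary-precision complex-order parabolic cylinder functions
    D_nu; the zero-frequency limit equals the slope of the f-I curve.
    """
    p = as_dimensionless(params)
    if state.r0 <= 0:
        raise ValueError("susceptibility needs a positive stationary rate")
    sD = math.sqrt(p.D)
    zT = (state.I0 - p.V_T) / sD
    zR = (state.I0 - p.V_R) / sD
    delta = (p.V_R ** 2 - p.V_T ** 2 + 2.0 * state.I0 * (p.V_T - p.V_R)) / (4.0 * p.D)
    with mp.workdps(30):
        iw = 1j * mp.mpf(omega)
        nu = -iw
        e_delta = mp.e ** delta
        num = mp.pcfd(nu - 1, zT) - e_delta * mp.pcfd(nu - 1, zR)
        den = (mp.pcfd(nu, zT)
               - e_delta * mp.e ** (-iw * p.tau_ref / p.tau_m) * mp.pcfd(nu, zR))
        G = state.r0 / sD * (iw / (iw + 1)) * num / den
    return complex(G)


def _conditions(I_E: float, omega: float, params, state=None):
    p = as_dimensionless(params)
    st = state or stationary_state(I_E, p)
    G = susceptibility(omega, st, p)
    amp = p.K * abs(G) - 1.0
    phase = math.pi + math.atan2(G.imag, G.real) - omega * p.delta / p.tau_m
    return amp, phase


def _solve_phase(I_E: float, params, f_lo: float = 100.0, f_hi: float = 600.0,
                 df: float = 2.0, state=None) -> float | None:
    """Angular frequency (1/tau_m units) solving the phase condition,
    from a scan over [f_lo, f_hi] Hz plus bisection."""
    p = as_dimensionless(params)
    st = state or stationary_state(I_E, p)

    def phase(om: float) -> float:
        return _conditions(I_E, om, p, state=st)[1]

    to_om = 2.0 * math.pi * p.tau_m / 1000.0      # Hz -> dimensionless omega
    oms = np.arange(f_lo, f_hi + df, df) * to_om
    prev = phase(oms[0])
    for om0, om1 in zip(oms[:-1], oms[1:]):
        cur = phase(om1)
        if prev == 0.0:
            return float(om0)
        if prev * cur < 0:
            return float(brentq(phase, om0, om1, xtol=1e-10))
        prev = cur
    return None


def hopf_point(params, ie_lo: float = 0.8, ie_hi: float = 3.0,
               tol: float = 1e-5) -> HopfPoint:
    """Locate the Hopf bifurcation of the stationary state.

    For each candidate drive the phase condition fixes omega; bisection
    on the drive then zeroes the amplitude condition ``K tau_m |G| = 1``
    (|G| grows with drive through r_0).
    """
    p = as_dimensionless(params)

    def amp_at(I_E: float):
        st = stationary_state(I_E, p)
        om = _solve_phase(I_E, p, state=st)
        if om is None:
            raise ValueError(f"no phase-condition root in the scan band at I_E={I_E}")
        return _conditions(I_E, om, p, state=st)[0], om, st

    a_lo, _, _ = amp_at(ie_lo)
    a_hi, _, _ = amp_at(ie_hi)
    if a_lo * a_hi > 0:
        raise ValueError(f"[{ie_lo}, {ie_hi}] does not bracket the Hopf point")
    lo, hi = ie_lo, ie_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        a_mid, _, _ = amp_at(mid)
        if a_mid * a_lo <= 0:
            hi = mid
        else:
            lo = mid
            a_lo = a_mid
    ie_crit = 0.5 * (lo + hi)
    _, omega, st = amp_at(ie_crit)
    f_net = omega / (2.0 * math.pi) * 1000.0 / p.tau_m
    return HopfPoint(IE_crit=ie_crit,
                     I_ext_crit_nA=drive_to_physical(ie_crit),
                     f_net_hz=f_net, f_unit_hz=st.r0_hz, omega=omega)


__all__ = ["StationaryState", "HopfPoint", "lif_rate", "lif_rate_hz",
           "stationary_state", "susceptibility", "hopf_point"]
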