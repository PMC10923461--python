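"""Linear-drive cycle theory: constant-drive degeneracies, Lambert-W
root against direct numerical solution, sign laws, and chained-ramp
hysteresis."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from ripplenet.params import DimensionlessParams
from ripplenet import theory
from ripplenet.transient import (LinearCycleInput, chain_falling,
                                 chain_rising, cycle_map, mu_max_linear,
                                 mu_max_slope, t_off_linear, theory_ifa,
                                 theory_sim_error)


class TestConstantDriveLimit:
    def test_m_zero_reduces_exactly(self, defaults):
        ref = theory.constant_drive_solution(3.6, defaults, with_reset=True)
        cyc = cycle_map(LinearCycleInput(3.6, ref.mu_min, 0.0), defaults)
        assert cyc.f_inst == pytest.approx(ref.f_net, rel=1e-9)
        assert cyc.mu_max == pytest.approx(ref.mu_max, rel=1e-9)
        assert cyc.mu_min_next == pytest.approx(ref.mu_min, rel=1e-9)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_small_m_continuity(self, defaults, sign):
        m = sign * 1e-4
        ref = theory.constant_drive_solution(5.0, defaults, with_reset=True)
        cyc = cycle_map(LinearCycleInput(5.0, ref.mu_min, m), defaults)
        assert cyc.t_off == pytest.approx(
            theory.t_off(ref.mu_min, ref.mu_max, 5.0, defaults), rel=1e-3)
        assert cyc.mu_min_next == pytest.approx(ref.mu_min, rel=1e-3, abs=1e-3)


class TestTOffLambert:
    @pytest.mark.parametrize("m", [0.4, -0.4, 0.15, -0.15])
    def test_against_direct_root(self, defaults, m):
        """The Lambert-W closed form equals the numerical root of the
        upstroke equation mu(t) = mu_max."""
        p = defaults
        ie = 5.0
        mn = theory.mu_min(ie, p)
        mm, _ = mu_max_linear(LinearCycleInput(ie, mn, m), p)
        to = t_off_linear(LinearCycleInput(ie, mn, m), mm, p)

        def mu_of(t):  # drive anchored at t_off: IE(0) = ie - m*to
            i0 = ie - m * to
            return (i0 + m * t) - m * p.tau_m + \
                (m * p.tau_m + mn - i0) * math.exp(-t / p.tau_m)

        assert mu_of(to) == pytest.approx(mm, abs=1e-10)
        # and it is the first crossing
        tt = np.linspace(1e-6, to * 0.999, 200)
        assert np.all([mu_of(t) < mm for t in tt])

    def test_equal_extremes_give_zero(self, defaults):
        mm = theory.mu_max(5.0, defaults)
        to = t_off_linear(LinearCycleInput(5.0, mm, 0.0), mm, defaults)
        assert to == pytest.approx(0.0, abs=1e-12)

    def test_no_transient_solution_region(self, defaults):
        """Rising drive at low reference with a too-low start: the
        Lambert argument leaves the real domain (white region of the
        transient state space)."""
        inp = LinearCycleInput(1.2, -3.0, 0.4)
        mm, _ = mu_max_linear(inp, defaults)
        assert t_off_linear(inp, mm, defaults) is None


class TestSignLaws:
    @pytest.mark.parametrize("ie", [4.0, 5.0, 7.0])
    def test_mu_max_deviation_opposes_slope(self, defaults, ie):
        mm0 = theory.mu_max(ie, defaults)
        up, _ = mu_max_linear(LinearCycleInput(ie, 0.0, 0.4), defaults)
        dn, _ = mu_max_linear(LinearCycleInput(ie, 0.0, -0.4), defaults)
        assert up < mm0 < dn

    @pytest.mark.parametrize("ie", [4.0, 5.0, 7.0])
    def test_mu_min_next_deviation_follows_slope(self, defaults, ie):
        ref = theory.mu_min(ie, defaults)
        mn = theory.mu_min(ie, defaults)
        up = cycle_map(LinearCycleInput(ie, mn, 0.4), defaults)
        dn = cycle_map(LinearCycleInput(ie, mn, -0.4), defaults)
        assert up.mu_min_next > ref > dn.mu_min_next

    def test_asymptotic_start_is_slow_for_rising_drive(self, defaults):
        """Starting a cycle from the constant-drive minimum, rising
        drive lengthens and falling drive shortens the upstroke."""
        ref = theory.constant_drive_solution(5.0, defaults)
        up = cycle_map(LinearCycleInput(5.0, ref.mu_min, 0.4), defaults)
        dn = cycle_map(LinearCycleInput(5.0, ref.mu_min, -0.4), defaults)
        assert up.f_inst < ref.f_net < dn.f_inst


def test_perturbative_fallback_is_first_order(defaults):
    """Root-find and the first-order perturbative value agree to O(m^2)
    (Richardson: the difference shrinks ~4x when m halves)."""
    mm0 = theory.mu_max(5.0, defaults)
    slope = mu_max_slope(5.0, defaults)
    assert slope < 0
    diffs = []
    for m in (0.4, 0.2, 0.1):
        mm, pert = mu_max_linear(LinearCycleInput(5.0, 0.0, m), defaults)
        assert not pert
        diffs.append(abs(mm - (mm0 + m * slope)))
    assert diffs[0] / diffs[1] == pytest.approx(4.0, rel=0.25)
    assert diffs[1] / diffs[2] == pytest.approx(4.0, rel=0.25)


class TestChains:
    def test_rising_chain_anchored_at_plateau(self, defaults):
        ch = chain_rising(0.4, 8.9, 0.74, defaults)
        last = ch.cycles[-1]
        assert last.I_hat + 0.4 * defaults.delta == pytest.approx(8.9, abs=0.01)
        # consecutive cycles match drive at their boundaries
        for a, b in zip(ch.cycles[:-1], ch.cycles[1:]):
            assert a.I_hat + 0.4 * defaults.delta == pytest.approx(
                b.I_hat - 0.4 * b.t_off, abs=1e-6)
        assert ch.t_starts[-1] + ch.cycles[-1].T == pytest.approx(0.0, abs=1e-9)

    def test_falling_chain_retains_one_trailing_cycle(self, defaults):
        ch = chain_falling(-0.4, 8.9, 0.74, defaults)
        flags = [c.has_asymptotic_ref for c in ch.cycles]
        assert all(flags[:-1])
        # the ripple outlasts the drive level at which it started
        assert ch.cycles[-1].I_hat < ch.cycles[0].I_hat

    def test_hysteresis_sign_law(self, defaults):
        """Rising-ramp cycles run above, falling-ramp cycles below their
        asymptotic reference frequency, with at most one exception per
        ramp."""
        lo = theory.applicability_range(defaults).IE_min
        for direction, chain in (("up", chain_rising(0.4, 8.9, 0.74, defaults)),
                                 ("dn", chain_falling(-0.4, 8.9, 0.74, defaults))):
            violations = 0
            for c in chain.cycles:
                if c.I_hat < lo:
                    continue
                ref = theory.constant_drive_solution(c.I_hat, defaults).f_net
                if direction == "up" and c.f_inst < ref:
                    violations += 1
                if direction == "dn" and c.f_inst > ref:
                    violations += 1
            assert violations <= 1

    def test_plateau_hold_returns_asymptotic_cycles(self, defaults):
        """Vanishing ramp slope: every chained cycle sits at the
        asymptotic plateau frequency (no hysteresis without change in
        drive)."""
        ch = chain_falling(-1e-5, 8.9, 8.89, defaults)
        ref = theory.constant_drive_solution(8.9, defaults).f_net
        assert len(ch.cycles) >= 1
        for c in ch.cycles:
            assert c.f_inst == pytest.approx(ref, rel=1e-3)


class TestTheoryIfa:
    def test_slope_magnitude_decreases_for_slower_ramps(self, defaults):
        chis = [theory_ifa(m, defaults).chi_ifa for m in (0.4, 0.2, 0.1)]
        assert all(c < 0 for c in chis)
        assert abs(chis[0]) > abs(chis[1]) > abs(chis[2])

    def test_matches_printed_slope_at_default_ramp(self, defaults):
        res = theory_ifa(0.4, defaults)
        assert res.chi_ifa == pytest.approx(-2.60, rel=0.15)


class TestTheorySimError:
    def _series(self, t, f):
        from ripplenet.metrics import InstFreqSeries
        t = np.asarray(t, float)
        return InstFreqSeries(t, np.asarray(f, float), np.ones_like(t),
                              np.ones(t.size, bool))

    def test_identical_series_zero_error(self):
        pts = [(float(t), 200.0) for t in range(10)]
        sim = self._series([p[0] for p in pts], [p[1] for p in pts])
        assert theory_sim_error(pts, [sim]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_offset_recovered(self):
        pts = [(float(t), 220.0) for t in range(10)]
        sim = self._series([p[0] for p in pts], [200.0] * 10)
        assert theory_sim_error(pts, [sim]) == pytest.approx(0.10)

    def test_no_overlap_rejected(self):
        pts = [(100.0, 200.0)]
        sim = self._series([0.0, 1.0, 2.0], [200.0] * 3)
        with pytest.raises(ValueError):
            theory_sim_error(pts, [sim])
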