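"""Closed-form constant-drive theory: printed worked examples, limits,
monotonicity, and quadrature oracles for the feedback integrals."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erf

from ripplenet.params import DimensionlessParams
from ripplenet import theory
from ripplenet.theory import (NoOscillation, applicability_range,
                              constant_drive_solution, full_synchrony_drive,
                              mu_max, mu_min, mu_reset,
                              oscillation_drive_threshold, performance_scores,
                              saturation_of_mu_max, t_off)


class TestMuMax:
    def test_below_threshold_rejected(self, defaults):
        bound = oscillation_drive_threshold(defaults)
        assert bound == pytest.approx(0.56, abs=0.005)
        with pytest.raises(NoOscillation):
            mu_max(bound - 0.01, defaults)

    def test_weak_coupling_rejected(self):
        with pytest.raises(NoOscillation):
            mu_max(5.0, DimensionlessParams(K=0.3))

    def test_vanishing_delay_limit(self, defaults):
        p = DimensionlessParams(delta=1e-7)
        expected = 1.0 - math.sqrt(
            2 * p.D * math.log(p.K / math.sqrt(2 * math.pi * p.D)))
        assert mu_max(5.0, p) == pytest.approx(expected, abs=1e-5)

    def test_independent_of_mu_min(self, defaults):
        # the closed form takes no initial condition at all
        import inspect
        sig = inspect.signature(mu_max)
        assert "mu_min" not in sig.parameters

    def test_below_drive(self, defaults):
        for ie in (1.0, 3.6, 8.0):
            assert mu_max(ie, defaults) < ie


class TestSaturation:
    def test_at_threshold_half(self, defaults):
        assert saturation_of_mu_max(1.0, defaults) == pytest.approx(0.5)

    def test_three_sigma_above(self, defaults):
        mm = 1.0 + 3 * math.sqrt(defaults.D)
        assert saturation_of_mu_max(mm, defaults) == pytest.approx(0.9987,
                                                                   abs=2e-4)

    def test_far_below_zero(self, defaults):
        assert saturation_of_mu_max(-50.0, defaults) == pytest.approx(0.0)

    def test_monotone_in_mu_max(self, defaults):
        mms = np.linspace(0.2, 1.8, 50)  # away from the erf tails, where s is flat at double precision
        sats = [saturation_of_mu_max(m, defaults) for m in mms]
        assert np.all(np.diff(sats) > 0)


def test_mu_reset_limits(defaults):
    assert mu_reset(0.9, 0.0, defaults) == 0.9
    assert mu_reset(0.9, 1.0, defaults) == pytest.approx(-0.1)  # V_T - V_R = 1


class TestMuMin:
    def test_zero_coupling_is_pure_relaxation(self, defaults):
        """With K = 0 the feedback bracket vanishes and the downstroke is
        plain relaxation towards the drive."""
        mm = mu_max(3.6, defaults)
        assert theory._inhibition_bracket(
            3.6, mm, DimensionlessParams(K=0.0)) == 0.0

    def test_printed_cycle_at_drive_3p6(self, defaults):
        mn = mu_min(3.6, defaults, with_reset=False)
        assert mn == pytest.approx(0.23, abs=0.01)
        mm = mu_max(3.6, defaults)
        assert t_off(mn, mm, 3.6, defaults) + defaults.delta == pytest.approx(
            3.44, abs=0.05)

    def test_reset_lowers_mu_min(self, defaults):
        for ie in (3.0, 3.6, 6.0, 9.0):
            assert mu_min(ie, defaults, True) < mu_min(ie, defaults, False)

    def test_decreasing_in_drive(self, defaults):
        ar = applicability_range(defaults)
        grid = np.linspace(ar.IE_min, 0.85 * ar.IE_max, 40)
        vals = [mu_min(float(ie), defaults) for ie in grid]
        assert np.all(np.diff(vals) < 0)


class TestFeedbackBracketOracles:
    """The two erf brackets of the closed form against numerical
    quadrature of the downstroke integrals at the matching level of
    history approximation."""

    def _setup(self, defaults, ie):
        p = defaults
        mm = mu_max(ie, p)
        sq = math.sqrt(2 * math.pi * p.D)
        dens = lambda mu: math.exp(-(p.V_T - mu) ** 2 / (2 * p.D)) / sq
        return p, mm, dens

    @pytest.mark.parametrize("ie", [3.2, 3.6, 5.0, 8.0])
    def test_first_term_exact_for_linear_history(self, defaults, ie):
        p, mm, dens = self._setup(defaults, ie)
        lin = lambda x: mm - (ie - mm) * x / p.tau_m
        val = quad(lambda s: dens(lin(p.delta - s)), 0, p.delta)[0]
        first = p.K * (ie - mm) / p.tau_m * val
        e1 = math.exp(p.delta / p.tau_m)
        phi = lambda t: (p.V_T - mm + (ie - mm) * (p.delta - t) / p.tau_m) \
            / math.sqrt(2 * p.D)
        closed = 0.5 * p.K * (erf(phi(0.0)) - erf(phi(p.delta)))
        assert first == pytest.approx(closed, rel=1e-9)

    @pytest.mark.parametrize("ie", [3.6, 5.0, 8.0])
    def test_second_term_matches_exponential_history(self, defaults, ie):
        """The Gaussian-product term derives from the exponential
        upstroke history with the exponentials linearized inside the
        integral; quadrature with the full exponential history agrees
        to a few percent."""
        p, mm, dens = self._setup(defaults, ie)
        hist = lambda x: ie - (ie - mm) * math.exp(x / p.tau_m)
        val = quad(lambda s: dens(hist(2 * p.delta - s)) * dens(hist(p.delta - s)),
                   0, p.delta)[0]
        second = p.K ** 2 * (ie - mm) * math.exp(p.delta / p.tau_m) / p.tau_m * val
        e1 = math.exp(p.delta / p.tau_m)
        e2 = math.exp(2 * p.delta / p.tau_m)
        psi = lambda t: (-(ie - mm) * (e2 + 1) * (p.tau_m + p.delta - t)
                         + p.tau_m * (ie - p.V_T) * (e1 + 1)) \
            / (math.sqrt(2 * p.D * (e2 + 1)) * p.tau_m)
        c = (p.V_T - ie) ** 2 * (1 - e1) ** 2 / (e2 + 1)
        closed = (0.5 * p.K * p.K / math.sqrt(2 * math.pi * p.D)
                  * math.exp(-c / (2 * p.D)) * e1 / math.sqrt(e2 + 1)
                  * (erf(psi(p.delta)) - erf(psi(0.0))))
        assert closed == pytest.approx(second, rel=0.06)


class TestPrintedFrequencies:
    def test_without_reset(self, defaults):
        sol = constant_drive_solution(3.6, defaults, with_reset=False)
        assert sol.f_net == pytest.approx(290.7, abs=0.5)
        assert sol.T == sol.t_off + defaults.delta
        assert sol.f_unit == pytest.approx(sol.s * sol.f_net)

    def test_with_reset(self, defaults):
        sol = constant_drive_solution(3.6, defaults, with_reset=True)
        assert sol.f_net == pytest.approx(235.8, abs=0.5)
        assert sol.T == pytest.approx(4.24, abs=0.02)


class TestFullSynchrony:
    def test_exceeds_simulation_estimate_slightly(self, defaults):
        # the closed form deliberately overestimates the simulated ~8.9
        val = full_synchrony_drive(defaults)
        assert 8.9 < val < 11.0

    def test_noise_free_limit_approaches_threshold(self):
        vals = [full_synchrony_drive(DimensionlessParams(D=d))
                for d in (0.04, 1e-3, 1e-5, 1e-9)]
        assert np.all(np.diff(vals) < 0)
        # approaches the threshold (slowly, ~ sqrt(D log 1/D))
        assert vals[-1] == pytest.approx(1.0, abs=0.01)

    def test_increases_with_coupling_and_noise(self, defaults):
        base = full_synchrony_drive(defaults)
        assert full_synchrony_drive(DimensionlessParams(K=8.0)) > base
        assert full_synchrony_drive(DimensionlessParams(D=0.08)) > base


class TestApplicability:
    def test_default_range(self, defaults):
        ar = applicability_range(defaults)
        assert ar.IE_min == pytest.approx(2.85, abs=0.05)
        assert ar.IE_max == pytest.approx(full_synchrony_drive(defaults))
        assert ar.upper_constraint == "single-spike"

    def test_high_noise_weak_coupling_corner(self):
        """For high noise and weak coupling mu_min rises again at strong
        drive and the subthreshold condition also binds from above."""
        p = DimensionlessParams(K=1.4, D=0.36)
        try:
            ar = applicability_range(p)
            assert ar.upper_constraint == "subthreshold" or ar.IE_max < \
                full_synchrony_drive(p)
        except NoOscillation:
            pass  # fully empty range is the extreme version of the corner


class TestMonotonicity:
    def test_s_and_mu_max_increase_with_drive(self, defaults):
        ar = applicability_range(defaults)
        grid = np.linspace(ar.IE_min, ar.IE_max, 60)
        sols = [constant_drive_solution(float(ie), defaults) for ie in grid]
        assert np.all(np.diff([c.s for c in sols]) > 0)
        assert np.all(np.diff([c.mu_max for c in sols]) > 0)


class TestPerformanceScores:
    def test_identical_curves(self):
        f = np.array([300.0, 250.0, 200.0])
        sc = performance_scores([3, 4, 5], f, f, IE_crit_sim=1.48,
                                IE_full_sim=8.9, IE_min=3.0, IE_max=8.9)
        assert sc.chi_err == 0.0
        assert sc.chi_p == sc.chi_appl

    def test_full_coverage(self):
        f = np.array([300.0, 250.0])
        sc = performance_scores([2, 3], f, f * 1.1, IE_crit_sim=1.5,
                                IE_full_sim=9.0, IE_min=1.5, IE_max=9.0)
        assert sc.chi_appl == 1.0
        assert sc.chi_err == pytest.approx(1 / 11, rel=1e-6)

    def test_product_identity_random(self):
        rng = np.random.default_rng(7)
        fs = rng.uniform(100, 300, 10)
        ft = fs * rng.uniform(0.8, 1.2, 10)
        sc = performance_scores(np.arange(10), ft, fs, 1.0, 9.0, 3.0, 8.0)
        assert sc.chi_p == pytest.approx(sc.chi_appl * (1 - sc.chi_err))
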