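"""Closed-form cable solutions versus the fine-grid compartmental oracle."""

import numpy as np
import pytest

from sensillum.cable_analytics import (
    analytic_steady, analytic_transient, dimensionless_conductance,
    steady_rp_base, steady_rp_profile, steady_sp, transient_small_signal,
    transient_steady_limit,
)
from sensillum.sensillum_network import steady_state_simplified


class TestSteadyState:
    def test_zero_conductance_gives_zero_everywhere(self, params):
        d = params.derived
        assert steady_rp_base(0.0, d.l_d, d.r_in) == 0.0
        assert steady_sp(0.0, d.l_d, d.r_in, d.a, d.beta) == 0.0
        x = np.linspace(0, d.l_d, 20)
        assert np.all(steady_rp_profile(x, 0.0, d.l_d, d.r_in) == 0)

    def test_profile_monotone_decreasing_tip_to_base(self, params):
        d = params.derived
        x = np.linspace(0, d.l_d, 100)
        for gp in (0.1, 1.0, 5.0):
            g = dimensionless_conductance(d, gp)
            prof = steady_rp_profile(x, g, d.l_d, d.r_in)
            assert np.all(np.diff(prof) < 0)

    def test_profile_continuous_with_base_value(self, params):
        d = params.derived
        g = dimensionless_conductance(d, 2.0)
        assert steady_rp_profile(d.l_d, g, d.l_d, d.r_in) == pytest.approx(
            steady_rp_base(g, d.l_d, d.r_in), rel=1e-12)

    def test_rp_base_increasing_and_saturating_in_g(self, params):
        d = params.derived
        gs = np.logspace(-3, 3, 40)
        rp = np.array([steady_rp_base(g, d.l_d, d.r_in) for g in gs])
        assert np.all(np.diff(rp) > 0)
        # saturation: secant slope decreases
        assert rp[-1] / gs[-1] < rp[0] / gs[0]

    def test_tip_to_base_drop_increases_with_conductance(self, params):
        d = params.derived
        drops = []
        for gp in (0.1, 1.0, 5.0):
            g = dimensionless_conductance(d, gp)
            p = steady_rp_profile(np.array([0.0, d.l_d]), g, d.l_d, d.r_in)
            drops.append(p[0] - p[1])
        assert np.all(np.diff(drops) > 0)

    def test_position_outside_dendrite_rejected(self, params):
        d = params.derived
        with pytest.raises(ValueError):
            steady_rp_profile(d.l_d + 0.1, 1.0, d.l_d, d.r_in)

    def test_sp_over_rp_ratio_independent_of_batteries(self, params):
        """With E_p = 0, scaling every battery jointly leaves SP/RP_b
        unchanged (it depends only on resistance ratios and length)."""
        d = params.derived
        g = dimensionless_conductance(d, 2.0)

        def ratio(E_ld):
            return (steady_sp(g, d.l_d, d.r_in, d.a, d.beta, E_ld=E_ld)
                    / steady_rp_base(g, d.l_d, d.r_in, E_ld=E_ld))

        assert ratio(-97.0) == pytest.approx(ratio(-48.5), rel=1e-12)
        assert ratio(-97.0) == pytest.approx(ratio(-194.0), rel=1e-12)

    def test_dimensional_rescaling_invariance(self, params):
        """Scaling every resistivity (and lumped resistance) by a common
        factor preserves the dimensionless groups, so the same dimensionless
        conductance gives the same potentials."""
        k = 2.0
        b = params.base
        ps2 = params.with_base(
            rho_ld=k * b.rho_ld, rho_e=k * b.rho_e, rho_i=k * b.rho_i,
            rho_ls=k * b.rho_ls, R_api=k * b.R_api, R_bas=k * b.R_bas,
            rho_bas=k * b.rho_bas)
        d1, d2 = params.derived, ps2.derived
        assert d2.l_d == pytest.approx(d1.l_d, rel=1e-12)
        assert d2.r_in == pytest.approx(d1.r_in, rel=1e-12)
        assert d2.a == pytest.approx(d1.a, rel=1e-12)
        # G_p scaled by 1/k gives the same dimensionless g, hence the same RP
        rp1, sp1 = analytic_steady(d1, 1.0)
        rp2, sp2 = analytic_steady(d2, 1.0 / k)
        assert rp2 == pytest.approx(rp1, rel=1e-12)
        assert sp2 == pytest.approx(sp1, rel=1e-12)

    def test_fine_grid_compartmental_oracle(self, params):
        """N = 2000 compartments agree with the closed forms to < 0.05%."""
        d = params.derived
        sc = params.scale(2000)
        for gp in (0.01, 5.0):
            rp_a, sp_a = analytic_steady(d, gp)
            ss = steady_state_simplified(sc, gp)
            assert abs(ss.RP_b - rp_a) / abs(rp_a) < 5e-4
            assert abs(ss.SP - sp_a) / abs(sp_a) < 5e-4


class TestTransient:
    def test_zero_step_is_identically_zero(self, params):
        d = params.derived
        v = transient_small_signal(np.array([0.0, 0.2]), np.array([0.5, 2.0]),
                                   0.0, d.l_d)
        assert np.all(v == 0)

    def test_long_time_limit_matches_closed_form(self, params):
        d = params.derived
        g = dimensionless_conductance(d, 0.1)
        x = np.linspace(0, d.l_d, 7)
        v_inf = transient_small_signal(x, np.array([60.0]), g, d.l_d)[0]
        v_ss = transient_steady_limit(x, g, d.l_d)
        assert np.allclose(v_inf, v_ss, rtol=1e-6, atol=1e-8)

    def test_starts_at_zero_and_rises_monotonically_at_tip(self, params):
        d = params.derived
        g = dimensionless_conductance(d, 0.1)
        t = np.linspace(0.0, 5.0, 60)
        v = transient_small_signal(np.array([0.0]), t, g, d.l_d)[:, 0]
        assert abs(v[0]) < 1e-9
        assert np.all(np.diff(v) > -1e-12)

    def test_agrees_with_compartmental_step_response(self, params, scale40):
        """The series solution tracks the N = 40 circuit within the stated
        band for conductance steps up to 0.2 nS."""
        from sensillum.sensillum_network import StepProtocol, \
            integrate_simplified
        d = params.derived
        t = np.arange(0.0, 50.0, 0.1)
        x_um = np.array([5.5, 110.0, 220.0])
        nodes = [0, 19, 39]
        for gp in (0.05, 0.2):
            tr = integrate_simplified(scale40, StepProtocol(gp), t_eval=t)
            ana = analytic_transient(d, gp, x_um, t)
            num = tr.RP[:, nodes]
            dev = np.max(np.abs(num - ana), axis=0) / np.max(np.abs(num),
                                                             axis=0)
            assert np.all(dev < 0.16)
            # approximation quality degrades from tip to base
            assert dev[0] < dev[-1]
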