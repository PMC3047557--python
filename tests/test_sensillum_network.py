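"""Circuit assembly, resting state, integration and RP/SP extraction."""

import numpy as np
import pytest

from sensillum.biochem_drive import DriveProtocol
from sensillum.channels import lumped_conductance
from sensillum.sensillum_network import (
    SensillumCircuit, SquareProtocol, StepProtocol, extract_potentials,
    integrate_complete, integrate_simplified, kirchhoff_residuals,
    leak_and_axial_currents, resting_state, steady_state_simplified,
)


class TestRestingState:
    def test_zero_currents_everywhere(self, params, scale40):
        rest = resting_state(scale40)
        snap = leak_and_axial_currents(rest, scale40)
        assert np.max(np.abs(snap.I_ld)) < 1e-9
        assert np.max(np.abs(snap.I_i)) < 1e-9
        assert np.max(np.abs(snap.I_e)) < 1e-9
        assert abs(snap.I_ls) < 1e-9 and abs(snap.I_a) < 1e-9

    def test_transmembrane_potential_pinned_at_leak_battery(self, params,
                                                            scale40):
        rest = resting_state(scale40)
        assert np.allclose(rest.dV, params.derived.E_ld)
        assert rest.V_is == pytest.approx(params.derived.E_ls)
        # lymph sits at the transepithelial potential above hemolymph
        assert rest.V_a == pytest.approx(-params.derived.E_a)

    def test_inconsistent_batteries_solved_numerically(self, params):
        from dataclasses import replace

        from sensillum.parameters import scale_to_compartments
        d_bad = replace(params.derived, E_ld=-90.0)   # != E_ls + E_a
        sc = scale_to_compartments(d_bad, params.channels, 10)
        rest = resting_state(sc)
        assert np.all(np.isfinite(rest.dV))
        # a standing circulating current now flows: soma off its battery
        assert rest.V_is != pytest.approx(params.derived.E_ls, abs=1e-6)

    def test_rp_sp_zero_without_stimulus(self, scale40):
        tr = integrate_simplified(scale40, StepProtocol(0.0), t_end=50.0)
        RP, RP_b, RP_s, SP = extract_potentials(tr)
        assert np.max(np.abs(RP)) < 1e-9
        assert np.max(np.abs(SP)) < 1e-9
        assert np.max(np.abs(RP_s)) < 1e-9


class TestAxialSolve:
    def test_uniform_intracellular_offset_leaves_axial_currents_zero(
            self, scale40):
        """Adding a constant to every intracellular node changes no
        difference, hence no axial intracellular current."""
        circ = SensillumCircuit(scale40)
        rest = circ.rest_vector()
        snap = leak_and_axial_currents(resting_state(scale40), scale40)
        assert np.max(np.abs(snap.I_i)) < 1e-9

    def test_external_solve_satisfies_node_constraint(self, params, rng):
        """For arbitrary states the solved lymph potentials make the net
        axial current into each intracellular node equal the net axial
        current out of the matching lymph node."""
        sc = params.scale(7)
        circ = SensillumCircuit(sc)
        dV = params.derived.E_ld + rng.normal(scale=10.0, size=7)
        V_is, V_a = -55.0, 30.0
        W = circ.solve_external(dV, V_is, V_a)
        V_id = W + dV
        for j in range(7):
            into = 0.0
            if j > 0:
                into += sc.g_ic * (V_id[j - 1] - V_id[j])
                into += sc.g_ec * (W[j - 1] - W[j])
            if j < 6:
                into += sc.g_ic * (V_id[j + 1] - V_id[j])
                into += sc.g_ec * (W[j + 1] - W[j])
            else:
                into += sc.g_ic * (V_is - V_id[j])
                into += sc.g_ec * (V_a - W[j])
            assert into == pytest.approx(0.0, abs=1e-8)

    def test_kirchhoff_residuals_along_trajectory(self, scale40):
        tr = integrate_simplified(scale40, SquareProtocol(2.0, 0.0, 20.0),
                                  t_end=40.0, dt=0.5)
        res = kirchhoff_residuals(tr, scale40)
        # residual relative to the axial current scale
        scale = scale40.g_ic * np.max(np.abs(np.diff(tr.V_ed + tr.dV, axis=1)))
        assert np.max(np.abs(res)) < 1e-6 * max(scale, 1.0)


class TestSimplifiedModel:
    def test_zero_conductance_stays_at_rest(self, scale40):
        tr = integrate_simplified(scale40, StepProtocol(0.0), t_end=30.0)
        assert np.max(np.abs(tr.RP)) < 1e-9

    def test_rp_positive_sp_negative(self, scale40):
        tr = integrate_simplified(scale40, SquareProtocol(1.0, 0.0, 50.0),
                                  t_end=80.0)
        assert tr.RP_s.max() > 1.0
        assert tr.SP.min() < -0.5
        # opposite signs throughout the response
        mask = tr.RP_s > 0.1 * tr.RP_s.max()
        assert np.all(tr.SP[mask] < 0)

    def test_step_matches_ode_solver_route(self, scale40):
        """The exact LTI propagation and the adaptive ODE solver agree."""
        t = np.arange(0.0, 30.0, 0.5)
        tr_lti = integrate_simplified(scale40, StepProtocol(0.5), t_eval=t)
        g = np.full(scale40.N, 0.5 / scale40.N)
        tr_ode = integrate_simplified(scale40, lambda tm: g, t_eval=t,
                                      rtol=1e-10, atol=1e-12)
        assert np.allclose(tr_lti.RP, tr_ode.RP, atol=1e-4)
        assert np.allclose(tr_lti.SP, tr_ode.SP, atol=1e-4)

    def test_steady_state_matches_long_integration(self, scale40):
        ss = steady_state_simplified(scale40, 2.0)
        tr = integrate_simplified(scale40, StepProtocol(2.0), t_end=200.0)
        assert tr.RP_b[-1] == pytest.approx(ss.RP_b, rel=1e-6)
        assert tr.SP[-1] == pytest.approx(ss.SP, rel=1e-6)

    def test_sp_rp_ratio_nearly_independent_of_amplitude(self, scale40):
        """Steady SP is proportional to RP; the ratio is dose-independent to
        within ~1% over the physiological conductance range (the residual
        variation comes from the g-dependence of the spatial profile)."""
        ratios = [steady_state_simplified(scale40, gp).SP
                  / steady_state_simplified(scale40, gp).RP_b
                  for gp in (0.064, 0.5, 4.0)]
        assert np.allclose(ratios, ratios[0], rtol=0.02)
        assert -0.45 < ratios[0] < -0.25       # roughly one third, negative

    def test_small_signal_linearity(self, scale40):
        """For G_p -> 0 the steady RP is linear in G_p."""
        r1 = steady_state_simplified(scale40, 1e-4).RP_s / 1e-4
        r2 = steady_state_simplified(scale40, 2e-4).RP_s / 2e-4
        assert r1 == pytest.approx(r2, rel=1e-3)

    def test_negative_conductance_rejected(self, scale40):
        with pytest.raises(ValueError):
            integrate_simplified(scale40, StepProtocol(-1.0), t_end=10.0)
        with pytest.raises(ValueError):
            integrate_simplified(scale40, lambda t: np.full(scale40.N, -0.1),
                                 t_end=5.0)


class TestExtractPotentials:
    def test_outputs_zero_at_time_zero(self, scale40):
        tr = integrate_simplified(scale40, SquareProtocol(1.0, 5.0, 20.0),
                                  t_end=40.0)
        RP, RP_b, RP_s, SP = extract_potentials(tr)
        assert np.all(RP[0] == 0) and RP_s[0] == 0 and SP[0] == 0

    def test_not_starting_at_rest_refused(self, scale40):
        tr = integrate_simplified(scale40, StepProtocol(1.0), t_end=40.0)
        # restart from the depolarized end state: reference undefined
        y_end = np.concatenate([tr.dV[-1], [tr.V_is[-1], tr.V_a[-1]]])
        tr2 = integrate_simplified(scale40, StepProtocol(1.0), t_end=10.0,
                                   y0=y_end)
        with pytest.raises(ValueError, match="rest"):
            extract_potentials(tr2)


@pytest.fixture(scope="module")
def traj(params):
    """Complete-model run at a mid-range uptake, N = 10."""
    return integrate_complete(params.scale(10), DriveProtocol(), U=0.1,
                              t_end=4000.0, dt=2.0)


class TestCompleteModel:
    def test_zero_drive_stays_at_rest(self, params):
        sc = params.scale(10)
        drive = DriveProtocol(amplitudes={"IP3": 0.0, "DAG": 0.0})
        tr = integrate_complete(sc, drive, U=1.0, t_end=100.0, dt=1.0)
        assert np.max(np.abs(tr.RP)) < 1e-6
        assert np.max(np.abs(tr.SP)) < 1e-6

    def test_rp_rises_and_decays_sp_mirrors(self, traj):
        assert traj.RP_s.max() > 5.0
        assert traj.SP.min() < -2.0
        # decays after stimulus offset (slowly: the Cl- wave outlives the
        # pulse while Ca2+ is extruded, as for the measured potentials)
        k_off = np.argmin(np.abs(traj.t - 2500.0))
        assert traj.RP_s[-1] < 0.95 * traj.RP_s.max()
        assert np.all(np.diff(traj.RP_s[k_off:]) < 1e-6)

    def test_rp_height_declines_from_tip_to_base(self, traj):
        heights = traj.RP.max(axis=0)
        assert np.all(np.diff(heights) < 0)

    def test_calcium_stays_physiological(self, traj):
        ca = traj.modulators["Ca"]
        assert np.all(ca >= 0)
        assert np.max(ca) < 200.0

    def test_lumped_conductance_replay(self, params):
        """Replaying Eq.-21 equivalent conductances (and the somatic K+
        conductance) through the single-conductance circuit reproduces the
        complete model's potentials."""
        sc = params.scale(10)
        trc = integrate_complete(sc, DriveProtocol(), U=0.1, t_end=3000.0,
                                 dt=1.0)
        tc, gp, gk = trc.t, trc.g_p, np.asarray(trc.meta["G_K"])

        def g_of_t(tm):
            k = np.clip(np.searchsorted(tc, tm), 1, tc.size - 1)
            w = (tm - tc[k - 1]) / (tc[k] - tc[k - 1])
            return np.maximum((1 - w) * gp[k - 1] + w * gp[k], 0.0)

        trs = integrate_simplified(
            sc, g_of_t, t_eval=tc, rtol=1e-8, atol=1e-10,
            G_K_of_t=lambda tm: float(np.interp(tm, tc, gk)))
        scale = np.max(np.abs(trc.RP))
        assert np.max(np.abs(trs.RP - trc.RP)) < 0.02 * scale
        assert np.max(np.abs(trs.SP - trc.SP)) < 0.02 * scale


def test_single_compartment_circuit_runs(params, scale1):
    tr = integrate_simplified(scale1, StepProtocol(1.0), t_end=50.0)
    assert tr.RP_b[-1] > 0
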