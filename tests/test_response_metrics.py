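"""Height/half-time extraction, EC50s, errors, amplification, sweeps."""

import numpy as np
import pytest

from sensillum.response_metrics import (
    DoseResponseCurve, amplification_ratios, characterize, ec50,
    parameter_sweep, relative_error, substitute_parameter,
)
from sensillum.sensillum_network import steady_state_simplified


class TestCharacterize:
    def test_saturating_exponential_closed_form(self):
        """A(1 - e^(-t/theta)) clamped at offset with decay theta' has
        tau_rise = theta ln 2 and tau_fall = theta' ln 2."""
        theta, theta_p, A = 0.3, 0.8, 5.0
        onset, offset = 0.0, 2.0
        t = np.linspace(0, 8, 16001)
        y = np.where(t < offset, A * (1 - np.exp(-t / theta)),
                     A * (1 - np.exp(-offset / theta))
                     * np.exp(-(t - offset) / theta_p))
        c = characterize(t, y, onset, offset)
        assert c.height == pytest.approx(A * (1 - np.exp(-offset / theta)),
                                         rel=1e-3)
        assert c.tau_rise == pytest.approx(theta * np.log(2), rel=1e-2)
        assert c.tau_fall == pytest.approx(theta_p * np.log(2), rel=1e-2)

    def test_negative_fall_time_when_decline_precedes_offset(self):
        """A transient that peaks and halves before stimulus offset gets a
        negative half-fall time (measured from the offset)."""
        t = np.linspace(0, 4, 4001)
        y = np.exp(-((t - 0.3) / 0.2) ** 2)      # pulse ends at t = 2
        c = characterize(t, y, 0.0, 2.0)
        assert c.tau_fall < 0

    def test_all_zero_curve(self):
        t = np.linspace(0, 1, 100)
        c = characterize(t, np.zeros_like(t), 0.0, 0.5)
        assert c.height == 0.0
        assert c.missing_rise and c.missing_fall

    def test_negative_going_curves_handled_by_sign(self):
        t = np.linspace(0, 6, 6001)
        y = -3.0 * (1 - np.exp(-t / 0.5))
        c = characterize(t, y, 0.0, 2.0)
        assert c.height == pytest.approx(-3.0, rel=1e-2)
        assert c.tau_rise == pytest.approx(0.5 * np.log(2), rel=1e-2)

    def test_grid_refinement_invariance(self):
        theta = 0.25
        for n in (201, 2001, 20001):
            t = np.linspace(0, 3, n)
            y = 1 - np.exp(-t / theta)
            c = characterize(t, y, 0.0, 3.0)
            assert c.tau_rise == pytest.approx(theta * np.log(2), rel=5e-2)

    def test_never_reaching_half_reported_missing(self):
        # transient that has already decayed below half when the analysis
        # window opens: no half-rise crossing exists after onset
        t = np.linspace(0, 4, 401)
        y = np.exp(-((t - 0.2) / 0.1) ** 2)
        c = characterize(t, y, 1.0, 2.0)
        assert c.missing_rise


class TestEc50:
    def test_exact_hill_curve_recovers_K(self):
        K, n = 0.07, 1.3
        d = np.logspace(-4, 2, 25)
        h = d**n / (K**n + d**n)
        assert ec50(d, h) == pytest.approx(K, rel=0.02)

    def test_ratio_of_ec50s_yields_sensitivity_gain(self):
        # two Hill curves with EC50s 11.75 and 0.069 -> ~170-fold gain
        d = np.logspace(-5, 3, 200)
        e1 = ec50(d, d / (11.75 + d))
        e2 = ec50(d, d / (0.069 + d))
        assert e1 / e2 == pytest.approx(11.75 / 0.069, rel=0.02)

    def test_curve_saturating_below_half_missing(self):
        d = np.logspace(-2, 2, 20)
        h = 0.4 * d / (1 + d)
        assert np.isnan(ec50(d, h))


class TestRelativeError:
    def test_exact_agreement(self):
        assert relative_error(3.2, 3.2) == 0.0

    def test_magnitude(self):
        assert relative_error(1.2, 1.0) == pytest.approx(0.2)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)


class TestAmplification:
    def test_unity_at_grid_maximum(self):
        G = np.array([0.01, 0.1, 1.0, 10.0])
        RP = np.array([0.5, 4.0, 20.0, 60.0])
        f_r = amplification_ratios(G, RP)
        assert f_r[-1] == pytest.approx(1.0)

    def test_linear_response_gives_constant_ratio(self):
        G = np.logspace(-2, 1, 7)
        f_r = amplification_ratios(G, 5.0 * G)
        assert np.allclose(f_r, 1.0)

    def test_zero_maximum_rejected(self):
        with pytest.raises(ValueError):
            amplification_ratios(np.array([1.0, 2.0]), np.zeros(2))


class TestParameterSweep:
    def test_dendrite_length_increases_rp_base(self, params):
        """RP_b grows monotonically with L_d at fixed conductivity."""
        sigma = 1.0 / (np.pi * params.base.L_d * params.base.D_i)  # nS per um^2

        def metric(ps):
            G_p = sigma * np.pi * ps.base.L_d * ps.base.D_i
            return steady_state_simplified(ps.scale(20), G_p).RP_b

        df = parameter_sweep(params, "L_d", [60, 110, 220, 440, 880], metric)
        assert np.all(np.diff(df["metric"]) > 0)

    def test_soma_area_decreases_rp_base(self, params):
        def metric(ps):
            return steady_state_simplified(ps.scale(20), 1.0).RP_b

        df = parameter_sweep(params, "S_s", [72, 144, 288, 576], metric)
        assert np.all(np.diff(df["metric"]) < 0)

    def test_gmk_raises_sp_to_rp_ratio_linearly(self, params):
        """The SP/RP_s height ratio grows (near-linearly) with the maximal
        K+ conductance at fixed somatic activation."""
        from sensillum.channels import k_conductance

        def metric(ps):
            sc = ps.scale(20)
            ss = steady_state_simplified(
                sc, 1.0,
                G_K_func=lambda V: k_conductance(1.0, V, ps.channels.K))
            return abs(ss.SP / ss.RP_s)

        values = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        df = parameter_sweep(params, "G_MK", values, metric)
        r = df["metric"].to_numpy()
        assert np.all(np.diff(r) > 0)
        # near-linear growth: second differences small vs first differences
        assert np.max(np.abs(np.diff(r, 2))) < 0.2 * np.max(np.diff(r))

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(KeyError):
            substitute_parameter(params, "no_such_knob", 1.0)


def test_dose_response_curve_container():
    d = np.logspace(-2, 1, 8)
    h = 30 * d / (0.1 + d)
    c = DoseResponseCurve(doses=d, heights=h, tau_rise=np.full(8, 0.1),
                          tau_fall=np.full(8, 3.0))
    assert np.all((0 <= c.relative_heights) & (c.relative_heights <= 1))
    assert c.ec50 == pytest.approx(0.1, rel=0.05)
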