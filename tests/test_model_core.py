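import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from ecpella import units
from ecpella.model_core import (ChamberParams, CircuitParams, SimState,
                                ScenarioPreset, activation, chamber_pressure,
                                circulation_rhs, compartment_pressures,
                                elastance_waveform, valve_flow,
                                STATE_ORDER)


@pytest.fixture
def lv_failure_chamber():
    return ChamberParams(role="LV", E_es=0.4, E_min=0.08, V0=5.0,
                         edpvr_alpha=0.2, edpvr_beta=0.02,
                         t_activation_onset=0.0, t_activation_duration=0.36)


# --- independent activation oracle: direct double-Hill tabulation ----------

def activation_oracle(chamber, n=200001):
    """Dense tabulation of the normalized double-Hill twitch, written
    independently of the implementation (vectorized, own normalization)."""
    s1, m1, s2, m2 = 0.303, 1.9, 0.508, 21.9
    x = np.linspace(0.0, 1.0, n)
    h = (x / s1) ** m1 / (1 + (x / s1) ** m1) / (1 + (x / s2) ** m2)
    h = h / h.max()
    phases = (chamber.t_activation_onset
              + x * chamber.t_activation_duration) % 1.0
    return phases, h


class TestElastanceWaveform:
    def test_late_diastole_returns_emin(self, lv_failure_chamber):
        # activation window is [0, 0.36); late diastole is fully inactive
        for tc in (0.5, 0.7, 0.95):
            assert elastance_waveform(tc, lv_failure_chamber) == \
                pytest.approx(lv_failure_chamber.E_min)

    def test_peak_equals_ees(self, lv_failure_chamber):
        grid = np.linspace(0, 1, 20001, endpoint=False)
        peak = max(elastance_waveform(t, lv_failure_chamber) for t in grid)
        assert peak == pytest.approx(0.4, rel=1e-6)

    def test_matches_tabulated_oracle(self, lv_failure_chamber):
        phases, a_oracle = activation_oracle(lv_failure_chamber, n=2001)
        ch = lv_failure_chamber
        for ph, a in zip(phases[::100], a_oracle[::100]):
            expected = ch.E_min + a * (ch.E_es - ch.E_min)
            assert elastance_waveform(float(ph), ch) == \
                pytest.approx(expected, rel=1e-4, abs=1e-9)

    def test_half_activation_midpoint(self, lv_failure_chamber):
        # find a phase where the oracle says a = 0.5 exactly (by bisection on
        # the rising limb) and check E there is the midpoint
        ch = lv_failure_chamber

        def a_of_x(x):
            s1, m1, s2, m2 = 0.303, 1.9, 0.508, 21.9
            raw = (x / s1) ** m1 / (1 + (x / s1) ** m1) / (1 + (x / s2) ** m2)
            xs = np.linspace(0, 1, 200001)
            norm = ((xs / s1) ** m1 / (1 + (xs / s1) ** m1)
                    / (1 + (xs / s2) ** m2)).max()
            return raw / norm

        x_half = brentq(lambda x: a_of_x(x) - 0.5, 1e-6, 0.45)
        tc = (ch.t_activation_onset + x_half * ch.t_activation_duration) % 1.0
        expected = ch.E_min + 0.5 * (ch.E_es - ch.E_min)
        assert elastance_waveform(tc, ch) == pytest.approx(expected, rel=1e-5)

    def test_periodic_wraparound(self, lv_failure_chamber):
        assert elastance_waveform(-0.8, lv_failure_chamber) == \
            pytest.approx(elastance_waveform(0.2, lv_failure_chamber))
        assert elastance_waveform(1.2, lv_failure_chamber) == \
            pytest.approx(elastance_waveform(0.2, lv_failure_chamber))

    @given(tc=st.floats(min_value=-5, max_value=5,
                        allow_nan=False, allow_infinity=False))
    def test_bounded_between_emin_and_ees(self, tc):
        ch = ChamberParams(role="LV", E_es=0.4, E_min=0.08, V0=5.0,
                           edpvr_alpha=0.2, edpvr_beta=0.02,
                           t_activation_onset=0.0, t_activation_duration=0.36)
        e = elastance_waveform(tc, ch)
        assert ch.E_min - 1e-12 <= e <= ch.E_es + 1e-12


class TestChamberPressure:
    def test_espvr_intercept(self, lv_failure_chamber):
        # full activation at V = V0 gives exactly zero pressure
        p = chamber_pressure(lv_failure_chamber.V0, lv_failure_chamber.E_es,
                             lv_failure_chamber)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_edpvr_through_origin(self, lv_failure_chamber):
        p = chamber_pressure(0.0, lv_failure_chamber.E_min, lv_failure_chamber)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_full_activation_linear_espvr(self, lv_failure_chamber):
        p = chamber_pressure(105.0, lv_failure_chamber.E_es, lv_failure_chamber)
        assert p == pytest.approx(0.4 * 100.0)

    def test_blend_weights(self, lv_failure_chamber):
        ch = lv_failure_chamber
        V = 130.0
        e_mid = 0.5 * (ch.E_es + ch.E_min)
        expected = 0.5 * ch.espvr_pressure(V) + 0.5 * ch.edpvr_pressure(V)
        assert chamber_pressure(V, e_mid, ch) == pytest.approx(expected)


class TestValveFlow:
    def test_closed_on_negative_gradient(self):
        assert valve_flow(10.0, 15.0, A=3.0, R_valve=0.01) == 0.0
        assert valve_flow(10.0, 10.0, A=3.0, R_valve=0.01) == 0.0

    def test_pure_bernoulli_sqrt_law(self):
        # with R = 0, quadrupling the gradient doubles the flow
        q1 = valve_flow(14.0, 10.0, A=3.0, R_valve=0.0)
        q4 = valve_flow(26.0, 10.0, A=3.0, R_valve=0.0)
        assert q4 == pytest.approx(2.0 * q1, rel=1e-12)

    def test_against_bisection_oracle(self):
        A, R, rho, dp = 3.0, 0.01, 1.05, 10.0
        b = units.bernoulli_coefficient(A, rho)
        q_oracle = brentq(lambda q: R * q + b * q * q - dp, 0.0, 1e6,
                          xtol=1e-12)
        assert valve_flow(20.0, 10.0, A=A, R_valve=R, rho=rho) == \
            pytest.approx(q_oracle, rel=1e-9)

    @given(dp=st.floats(min_value=1e-3, max_value=200))
    @settings(max_examples=50)
    def test_strictly_increasing_in_gradient(self, dp):
        q1 = valve_flow(dp, 0.0, A=4.0, R_valve=0.005)
        q2 = valve_flow(dp * 1.01, 0.0, A=4.0, R_valve=0.005)
        assert q2 > q1


def make_params(**over):
    base = dict(R_MV=0.005, R_AV=0.03, R_TV=0.005, R_PAV=0.005,
                R_SZ0=0.035, R_PZ0=0.03,
                R_SA=0.5, R_SC=0.16, R_SV=0.04,
                R_PA=0.18, R_PC=0.14, R_PV=0.04,
                C_SA=2.0, C_SC=3.0, C_SV=20.0,
                C_PA=7.0, C_PC=4.0, C_PV=7.0,
                A_MV=4.0, A_AV=3.0, A_TV=5.0, A_PAV=3.5,
                HR=80.0, V_total=800.0, rho=1.05)
    base.update(over)
    return CircuitParams(**base)


def make_chambers():
    return {
        "LA": ChamberParams("LA", 0.3, 0.15, 8.0, 0.8, 0.04, 0.85, 0.17),
        "LV": ChamberParams("LV", 0.4, 0.08, 5.0, 0.2, 0.02, 0.0, 0.36),
        "RA": ChamberParams("RA", 0.25, 0.12, 8.0, 0.3, 0.03, 0.85, 0.17),
        "RV": ChamberParams("RV", 0.2, 0.05, 5.0, 0.3, 0.03, 0.0, 0.36),
    }


class TestCompartmentPressures:
    def test_zero_volume_zero_pressure(self):
        params = make_params()
        st_ = SimState(50, 120, 50, 120, 0.0, 60, 300, 40, 30, 50, t=0.4)
        p = compartment_pressures(st_, params, make_chambers())
        assert p["SAP"] == 0.0

    def test_linear_compliance(self):
        params = make_params(C_SA=2.0)
        st_ = SimState(50, 120, 50, 120, 180.0, 60, 300, 40, 30, 50, t=0.4)
        p = compartment_pressures(st_, params, make_chambers())
        assert p["SAP"] == pytest.approx(90.0)

    def test_full_snapshot_against_hand_table(self):
        # independent spreadsheet-style recomputation of all ten pressures
        params = make_params()
        chambers = make_chambers()
        t = 0.5  # late diastole at HR 80 (phase 0.667): all activations zero
        st_ = SimState(V_LA=40, V_LV=130, V_RA=45, V_RV=110,
                       V_SA=160, V_SC=66, V_SV=240, V_PA=49,
                       V_PC=24, V_PV=21, t=t)
        p = compartment_pressures(st_, params, chambers, t)
        phase = (t / 0.75) % 1.0
        for role, vname, pname in (("LA", "V_LA", "LAP"), ("LV", "V_LV", "LVP"),
                                   ("RA", "V_RA", "RAP"), ("RV", "V_RV", "RVP")):
            ch = chambers[role]
            # hand formula: a*Ees*(V-V0) + (1-a)*alpha*(exp(beta*V)-1)
            local = (phase - ch.t_activation_onset) % 1.0
            assert local >= ch.t_activation_duration  # inactive by design
            v = getattr(st_, vname)
            expected = ch.edpvr_alpha * (math.exp(ch.edpvr_beta * v) - 1.0)
            assert p[pname] == pytest.approx(expected, rel=1e-12)
        assert p["SAP"] == pytest.approx(160 / 2.0)
        assert p["SCP"] == pytest.approx(66 / 3.0)
        assert p["SVP"] == pytest.approx(240 / 20.0)
        assert p["PAP"] == pytest.approx(49 / 7.0)
        assert p["PCP"] == pytest.approx(24 / 4.0)
        assert p["PVP"] == pytest.approx(21 / 7.0)


class TestCirculationRhs:
    def test_equilibrium_gives_zero_vector(self):
        params = make_params()
        chambers = make_chambers()
        # construct a state with all compartments at the same pressure P*,
        # during complete diastole, devices off: no gradients, no flows
        p_star = 5.0
        vols = {}
        for role, key in (("LA", "V_LA"), ("LV", "V_LV"),
                          ("RA", "V_RA"), ("RV", "V_RV")):
            ch = chambers[role]
            vols[key] = math.log(p_star / ch.edpvr_alpha + 1.0) / ch.edpvr_beta
        for key, c in (("V_SA", params.C_SA), ("V_SC", params.C_SC),
                       ("V_SV", params.C_SV), ("V_PA", params.C_PA),
                       ("V_PC", params.C_PC), ("V_PV", params.C_PV)):
            vols[key] = p_star * c
        st_ = SimState(**vols, t=0.5)
        dV, flows = circulation_rhs(st_, params, chambers)
        assert np.allclose(dV, 0.0, atol=1e-12)
        assert all(abs(q) < 1e-12 for q in flows.values())

    def test_derivative_sum_is_zero(self):
        params = make_params()
        chambers = make_chambers()
        st_ = SimState(40, 130, 45, 110, 160, 66, 240, 49, 24, 21, t=0.1)
        dV, _ = circulation_rhs(st_, params, chambers,
                                q_impella_mls=40.0, q_vaecmo_mls=50.0)
        gross = np.sum(np.abs(dV))
        assert abs(dV.sum()) <= 1e-9 * max(gross, 1.0)

    def test_hand_traced_flow_balance(self):
        # diastolic state with mitral and tricuspid valves open; recompute
        # every edge flow by hand from the circuit topology
        params = make_params()
        chambers = make_chambers()
        st_ = SimState(60, 100, 60, 90, 160, 66, 240, 49, 24, 28, t=0.5)
        p = compartment_pressures(st_, params, chambers)
        dV, flows = circulation_rhs(st_, params, chambers)

        def orifice(dp, A, R):
            if dp <= 0:
                return 0.0
            b = units.bernoulli_coefficient(A, params.rho)
            return (-R + math.sqrt(R * R + 4 * b * dp)) / (2 * b)

        q_mv = orifice(p["LAP"] - p["LVP"], params.A_MV, params.R_MV)
        q_tv = orifice(p["RAP"] - p["RVP"], params.A_TV, params.R_TV)
        q_sa = (p["SAP"] - p["SCP"]) / params.R_SA
        q_sc = (p["SCP"] - p["SVP"]) / params.R_SC
        q_sv = (p["SVP"] - p["RAP"]) / params.R_SV
        q_pa = (p["PAP"] - p["PCP"]) / params.R_PA
        q_pc = (p["PCP"] - p["PVP"]) / params.R_PC
        q_pv = (p["PVP"] - p["LAP"]) / params.R_PV
        assert flows["Q_MV"] == pytest.approx(q_mv, rel=1e-12)
        assert flows["Q_TV"] == pytest.approx(q_tv, rel=1e-12)
        assert dV[STATE_ORDER.index("V_LA")] == pytest.approx(q_pv - q_mv)
        assert dV[STATE_ORDER.index("V_LV")] == pytest.approx(q_mv)  # AV closed
        assert dV[STATE_ORDER.index("V_SA")] == pytest.approx(-q_sa)
        assert dV[STATE_ORDER.index("V_SC")] == pytest.approx(q_sa - q_sc)
        assert dV[STATE_ORDER.index("V_SV")] == pytest.approx(q_sc - q_sv)
        assert dV[STATE_ORDER.index("V_PC")] == pytest.approx(q_pa - q_pc)

    def test_device_flows_redistribute_only(self):
        params = make_params()
        chambers = make_chambers()
        st_ = SimState(40, 130, 45, 110, 160, 66, 240, 49, 24, 21, t=0.2)
        dV0, _ = circulation_rhs(st_, params, chambers)
        dV1, fl = circulation_rhs(st_, params, chambers,
                                  q_impella_mls=40.0, q_vaecmo_mls=50.0)
        # Impella moves volume LV -> SA; ECMO SV -> SA
        assert fl["Q_impella"] == pytest.approx(40.0)
        assert fl["Q_vaecmo"] == pytest.approx(50.0)
        diff = dV1 - dV0
        assert diff[STATE_ORDER.index("V_LV")] == pytest.approx(-40.0)
        assert diff[STATE_ORDER.index("V_SV")] == pytest.approx(-50.0)
        assert diff[STATE_ORDER.index("V_SA")] == pytest.approx(90.0)

    @given(vols=st.lists(st.floats(min_value=0.5, max_value=400.0),
                         min_size=10, max_size=10),
           t=st.floats(min_value=0.0, max_value=3.0))
    @settings(max_examples=60, deadline=None)
    def test_conservation_property(self, vols, t):
        params = make_params()
        chambers = make_chambers()
        st_ = SimState(*vols, t=t)
        dV, flows = circulation_rhs(st_, params, chambers,
                                    q_impella_mls=30.0, q_vaecmo_mls=60.0)
        gross = np.sum(np.abs(dV))
        assert abs(dV.sum()) <= 1e-9 * max(gross, 1.0)
        for name in ("Q_MV", "Q_AV", "Q_TV", "Q_PAV"):
            assert flows[name] >= 0.0


class TestValidation:
    def test_positive_params_enforced(self):
        with pytest.raises(ValueError, match="strictly positive"):
            make_params(C_SA=-1.0)

    def test_chamber_invariants(self):
        with pytest.raises(ValueError):
            ChamberParams("LV", E_es=0.1, E_min=0.2, V0=5, edpvr_alpha=0.2,
                          edpvr_beta=0.02, t_activation_onset=0.0,
                          t_activation_duration=0.3)
        with pytest.raises(ValueError):
            ChamberParams("XX", E_es=0.4, E_min=0.1, V0=5, edpvr_alpha=0.2,
                          edpvr_beta=0.02, t_activation_onset=0.0,
                          t_activation_duration=0.3)

    def test_scenario_preset_zc_scale(self):
        p = ScenarioPreset("BVF_PH", 0.4, 0.2, 6.0, 11.7)
        assert p.Zc_scale == pytest.approx(7.5)
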