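"""Closed-loop Windkessel circulation with elastance chamber surrogates."""

import numpy as np
import pytest

from cardiomp import config as cfg
from cardiomp.circulation import (CircParams, ChamberSurrogate, CircState,
                                  chamber_pressure, valve_flow, fill_to_edv,
                                  circulation_rhs, CoupledHeart,
                                  apply_heart_failure, pv_metrics,
                                  cycle_metrics)


@pytest.fixture(scope="module")
def surrogate():
    return ChamberSurrogate(V0=15.0, c1=0.8, c2=0.02, k_act=0.04,
                            V_inf=148.0)


@pytest.fixture(scope="module")
def healthy_history():
    """Three steady cycles of the shipped healthy model."""
    model = cfg.standard_model()
    return model.simulate(cycles=3, dt=0.05)


class TestChamberPressure:
    def test_zero_at_unloaded_volume(self, surrogate):
        assert chamber_pressure(surrogate.V0, 0.0, surrogate) == 0.0

    def test_passive_strictly_increasing(self, surrogate):
        V = np.linspace(10.0, 200.0, 100)
        P = [chamber_pressure(v, 0.0, surrogate) for v in V]
        assert np.all(np.diff(P) > 0)

    def test_active_component_linear_in_tension(self, surrogate):
        V = surrogate.V0 + 40.0
        base = chamber_pressure(V, 0.0, surrogate)
        p1 = chamber_pressure(V, 20.0, surrogate) - base
        p2 = chamber_pressure(V, 40.0, surrogate) - base
        assert p2 == pytest.approx(2.0 * p1, rel=1e-12)


class TestValves:
    def test_no_flow_without_gradient(self):
        assert valve_flow(10.0, 10.0, 0.05) == 0.0

    def test_diode_blocks_reverse_flow(self):
        assert valve_flow(5.0, 20.0, 0.05) == 0.0

    def test_forward_flow_arithmetic(self):
        assert valve_flow(15.0, 5.0, 0.05) == pytest.approx(200.0)

    def test_smoothed_valve_approaches_hard_diode(self):
        hard = valve_flow(15.0, 5.0, 0.05)
        soft = valve_flow(15.0, 5.0, 0.05, smoothing=0.1)
        assert soft == pytest.approx(hard, rel=1e-3)
        assert valve_flow(5.0, 15.0, 0.05, smoothing=0.1) < 1e-3


class TestFilling:
    def test_filling_matches_closed_form(self, surrogate):
        """dV/dt = -k (V - Vinf) has the exact solution
        V(t) = Vinf + (V0 - Vinf) exp(-k t)."""
        k = 200.0
        t, V = fill_to_edv(surrogate, k_flow=k, V_start=50.0)
        expect = surrogate.V_inf + (50.0 - surrogate.V_inf) * np.exp(-k * t)
        np.testing.assert_allclose(V, expect, rtol=1e-6, atol=1e-6)

    def test_reaches_target(self, surrogate):
        t, V = fill_to_edv(surrogate)
        assert abs(V[-1] - surrogate.V_inf) < 1e-3 * surrogate.V_inf

    def test_sign_of_filling_flow(self, surrogate):
        # below target the flow is positive (filling)
        q = -200.0 * (100.0 - surrogate.V_inf)
        assert q > 0


class TestCirculationRhs:
    def test_equal_pressures_zero_tension_is_stationary(self):
        """All compartment pressures equal and no active tension: every
        valve/perfusion flow is zero and the state is stationary."""
        params = CircParams()
        P0 = 10.0
        vols = {c: getattr(params, f"Vu_{c}")
                + P0 * getattr(params, f"C_{c}")
                for c in ("sa", "sv", "pa", "pv", "la", "ra")}
        lv = ChamberSurrogate(V0=50.0, c1=1.0, c2=0.02, k_act=0.04)
        # chamber volume with passive pressure exactly P0
        V_ch = lv.V0 + np.log(P0 / lv.c1 + 1.0) / lv.c2
        state = CircState(V=vols, V_lv=V_ch, V_rv=V_ch)
        d = circulation_rhs(state, params, lv, lv, 0.0, 0.0)
        for c in ("sa", "sv", "pa", "pv", "la", "ra", "lv", "rv"):
            assert d[c] == pytest.approx(0.0, abs=1e-12)

    def test_negative_volume_aborts(self):
        params = CircParams()
        vols = {c: getattr(params, f"Vu_{c}") for c in
                ("sa", "sv", "pa", "pv", "la", "ra")}
        vols["sa"] = -1.0
        state = CircState(V=vols, V_lv=100.0, V_rv=100.0)
        with pytest.raises(RuntimeError, match="negative"):
            circulation_rhs(state, params, ChamberSurrogate(),
                            ChamberSurrogate(), 0.0, 0.0)


class TestClosedLoop:
    def test_blood_volume_conserved_over_10_cycles(self):
        model = cfg.standard_model()
        h = model.simulate(cycles=10, dt=0.05)
        drift = (h["V_total"].max() - h["V_total"].min()) / h["V_total"][0]
        assert drift < 1e-6

    def test_stroke_volumes_equalize_by_cycle_3(self, healthy_history):
        cyc_lv = cycle_metrics(healthy_history, "lv")
        cyc_rv = cycle_metrics(healthy_history, "rv")
        sv_lv, sv_rv = cyc_lv[-1]["SV"], cyc_rv[-1]["SV"]
        assert abs(sv_lv - sv_rv) / sv_lv < 0.02

    def test_limit_cycle_edv_stable_by_cycle_3(self):
        model = cfg.standard_model()
        h = model.simulate(cycles=4, dt=0.05)
        cyc = cycle_metrics(h, "lv")
        assert abs(cyc[3]["EDV"] - cyc[2]["EDV"]) / cyc[2]["EDV"] < 0.01

    def test_isovolumic_phases_exist(self, healthy_history):
        """Physiological run: mitral and aortic valves are never open
        simultaneously."""
        h = healthy_history
        both_open = (h["Q_mi"] > 1e-9) & (h["Q_ao"] > 1e-9)
        assert not both_open.any()

    def test_healthy_pressures_in_published_envelope(self, healthy_history):
        h = healthy_history
        last = h["t"] >= h["t"][-1] - h["period_ms"]
        assert h["P_ao"][last].max() == pytest.approx(126.71, rel=0.05)
        assert h["P_ao"][last].min() == pytest.approx(75.15, rel=0.05)

    def test_healthy_lv_ejection_fraction(self, healthy_history):
        m = pv_metrics(healthy_history, "lv")
        assert m["EF"] == pytest.approx(52.14, abs=3.0)


class TestHeartFailure:
    def test_transform_assertions(self, myo):
        circ, lv, rv, cl, cr = apply_heart_failure(
            CircParams(), ChamberSurrogate(), ChamberSurrogate(V0=10.0),
            myo, myo)
        assert cl.k_Ta == pytest.approx(0.5 * myo.k_Ta)
        assert circ.heart_rate == 80.0
        assert cr == myo                      # RV untouched
        assert rv == ChamberSurrogate(V0=10.0)

    def test_hf_lowers_lv_ef_more_than_rv(self, healthy_history):
        hf = cfg.heart_failure_model()
        h = hf.simulate(cycles=3, dt=0.05)
        ef_lv_hf = pv_metrics(h, "lv")["EF"]
        ef_rv_hf = pv_metrics(h, "rv")["EF"]
        ef_lv = pv_metrics(healthy_history, "lv")["EF"]
        ef_rv = pv_metrics(healthy_history, "rv")["EF"]
        assert ef_lv_hf < ef_lv
        assert ef_rv_hf < ef_rv
        assert (ef_lv - ef_lv_hf) > (ef_rv - ef_rv_hf)

    def test_hf_dilates_lv(self):
        hf = cfg.heart_failure_model()
        h = hf.simulate(cycles=3, dt=0.05)
        assert pv_metrics(h, "lv")["EDV"] == pytest.approx(299.0, rel=0.10)


class TestPvMetrics:
    def test_synthetic_cycle_from_published_table(self):
        """V(t) oscillating between the published EDV and ESV reproduces the
        published ejection fraction."""
        t = np.arange(0.0, 1000.0, 2.0)
        edv, sv = 148.39, 77.37
        V = edv - sv * 0.5 * (1.0 - np.cos(2 * np.pi * t / 1000.0))
        hist = {"t": t, "V_lv": V, "P_lv": np.zeros_like(t),
                "Q_ao": np.zeros_like(t), "Q_mi": np.zeros_like(t),
                "Q_pa": np.zeros_like(t), "Q_tri": np.zeros_like(t),
                "period_ms": 1000.0}
        m = pv_metrics(hist, "lv")
        assert m["EF"] == pytest.approx(52.14, abs=0.1)

    def test_constant_volume_gives_zero_ef(self):
        t = np.arange(0.0, 1000.0, 2.0)
        z = np.zeros_like(t)
        hist = {"t": t, "V_lv": np.full_like(t, 120.0), "P_lv": z,
                "Q_ao": z, "Q_mi": z, "Q_pa": z, "Q_tri": z,
                "period_ms": 1000.0}
        assert pv_metrics(hist, "lv")["EF"] == 0.0

    def test_ef_invariant_to_time_shift(self):
        t = np.arange(0.0, 1000.0, 2.0)
        z = np.zeros_like(t)
        V = 140.0 - 60.0 * 0.5 * (1 - np.cos(2 * np.pi * t / 1000.0))
        base = {"t": t, "P_lv": z, "Q_ao": z, "Q_mi": z, "Q_pa": z,
                "Q_tri": z, "period_ms": 1000.0}
        m1 = pv_metrics({**base, "V_lv": V}, "lv")
        m2 = pv_metrics({**base, "V_lv": np.roll(V, 100)}, "lv")
        assert m1["EF"] == pytest.approx(m2["EF"], rel=1e-12)

    def test_no_complete_cycle_rejected(self):
        hist = {"t": np.array([0.0, 2.0]), "V_lv": np.array([1.0, 2.0]),
                "P_lv": np.zeros(2), "Q_ao": np.zeros(2),
                "Q_mi": np.zeros(2), "Q_pa": np.zeros(2),
                "Q_tri": np.zeros(2), "period_ms": 1000.0}
        with pytest.raises(ValueError):
            pv_metrics(hist, "lv")
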