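#!/usr/bin/env python
"""Produce the versioned default parameter set (src/cardiomp/data/default_params.yaml).

Stages (all deterministic):
  1. cell       -- global time scale anchored on the epicardial APD90 (266 ms,
                   60-bpm pacing).
  2. tissue     -- sigma_f for 0.06 cm/ms fiber CV; Purkinje variant (k2 for
                   the x2 upstroke, rho_i for the x3 cable CV).
  3. healthy    -- least-squares fit of chamber surrogates + Windkessel
                   constants to the published healthy hemodynamics (LV/RV
                   EDV/ESV, aortic and pulmonary pressure envelopes).
  4. hf         -- dilation/volume knobs fitted to the published failing-heart
                   state (EDV 299 ml, EF 16.5%, peak aortic ~89 mmHg).
  5. pump       -- hydraulic coefficients fitted to the published pump
                   operating points (2.2/6.2 L/min at 2,100 RPM; 7 L/min
                   baseline after the ramp to 3,150 RPM).
  6. warmup     -- steady-state compartment volumes stored as initial
                   conditions.

Run from the repository root:  python scripts/calibrate_defaults.py
"""

import sys
import time
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import least_squares

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cardiomp.cell import calibrate_cell
from cardiomp.circulation import (CircParams, ChamberSurrogate, CoupledHeart,
                                  apply_heart_failure, pv_metrics,
                                  cycle_metrics)
from cardiomp.lvad import PumpParams, attach_pump, ramp_schedule
from cardiomp.tissue import calibrate_purkinje, calibrate_sigma_f

OUT = Path(__file__).resolve().parents[1] / "src" / "cardiomp" / "data" / "default_params.yaml"
CHECKPOINT = Path(__file__).resolve().parents[1] / "scratch" / "calibration_checkpoint.json"


def _plain(obj):
    """Recursively convert numpy scalars/arrays to built-in types."""
    import numpy as _np

    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, _np.generic):
        return obj.item()
    if isinstance(obj, _np.ndarray):
        return obj.tolist()
    return obj


def _checkpoint(key, value):
    import json

    CHECKPOINT.parent.mkdir(parents=True, exist_ok=True)
    data = {}
    if CHECKPOINT.exists():
        data = json.loads(CHECKPOINT.read_text())
    data[key] = _plain(value)
    CHECKPOINT.write_text(json.dumps(data, indent=1))


def _load_checkpoint(key):
    import json

    if CHECKPOINT.exists():
        return json.loads(CHECKPOINT.read_text()).get(key)
    return None

# published healthy hemodynamics used as calibration targets
HEALTHY_TARGETS = {
    "EDV_lv": 148.39, "ESV_lv": 71.02, "P_ao_max": 126.71, "P_ao_min": 75.15,
    "EDV_rv": 144.70, "ESV_rv": 67.05, "P_pa_max": 34.46, "P_pa_min": 13.44,
}
HF_TARGETS = {"EDV_lv": 299.0, "EF_lv": 16.5, "P_lv_max": 89.0}
PUMP_TARGETS = {"Q_base_2100": 2.2, "Q_peak_2100": 6.2, "Q_base_3150": 7.0}


def stage_cell():
    t0 = time.time()
    myo = calibrate_cell()
    print(f"[cell] k2 = {myo.k2:.6f} /ms  ({time.time()-t0:.0f} s)")
    return myo


def stage_tissue(myo):
    t0 = time.time()
    sigma_f = calibrate_sigma_f(myo, target_cv=0.06)
    cal = calibrate_purkinje(myo, sigma_f=sigma_f)
    print(f"[tissue] sigma_f = {sigma_f:.3f} mS/cm; purkinje k2 = "
          f"{cal.params.k2:.5f}, rho_i = {cal.params.rho_i:.5f} kOhm cm; "
          f"cv_ratio = {cal.cv_ratio:.4f}, upstroke (clamped/cable) = "
          f"{cal.upstroke_ratio_clamped:.4f}/{cal.upstroke_ratio_cable:.4f} "
          f"({time.time()-t0:.0f} s)")
    return sigma_f, cal


def _healthy_model(x, myo):
    k_lv, k_rv, v_sv, v_pv, r_sys, c_sa, r_pul, c_pa = x
    circ = CircParams(V0_sv=v_sv, V0_pv=v_pv, R_sys=r_sys, C_sa=c_sa,
                      R_pul=r_pul, C_pa=c_pa)
    lv = ChamberSurrogate(V0=15.0, c1=0.79, c2=0.02, k_act=k_lv,
                          V_inf=HEALTHY_TARGETS["EDV_lv"])
    rv = ChamberSurrogate(V0=10.0, c1=0.65, c2=0.015, k_act=k_rv,
                          V_inf=HEALTHY_TARGETS["EDV_rv"])
    return CoupledHeart(circ, lv, rv, cell_lv=myo, cell_rv=myo)


def stage_healthy(myo):
    t0 = time.time()
    tg = HEALTHY_TARGETS
    scale = np.array([tg["EDV_lv"], tg["ESV_lv"], tg["P_ao_max"],
                      tg["P_ao_min"], tg["EDV_rv"], tg["ESV_rv"],
                      tg["P_pa_max"], tg["P_pa_min"]])

    def residuals(x):
        model = _healthy_model(x, myo)
        h = model.simulate(cycles=4, dt=0.05)
        mlv, mrv = pv_metrics(h, "lv"), pv_metrics(h, "rv")
        t, last = h["t"], h["t"] >= h["t"][-1] - h["period_ms"]
        vals = np.array([
            mlv["EDV"], mlv["ESV"],
            h["P_ao"][last].max(), h["P_ao"][last].min(),
            mrv["EDV"], mrv["ESV"],
            h["P_pa"][last].max(), h["P_pa"][last].min(),
        ])
        return (vals - scale) / scale

    x0 = np.array([0.036, 0.0088, 2900.0, 200.0, 1.20, 1.4, 0.15, 4.5])
    lo = np.array([0.01, 0.002, 2500.0, 120.0, 0.6, 0.7, 0.05, 2.0])
    hi = np.array([0.10, 0.030, 3600.0, 420.0, 2.5, 3.0, 0.50, 12.0])
    fit = least_squares(residuals, x0, bounds=(lo, hi), diff_step=0.08,
                        xtol=1e-4, ftol=1e-4, max_nfev=60)
    print(f"[healthy] x = {np.round(fit.x, 5)}")
    print(f"[healthy] residuals (frac) = {np.round(fit.fun, 4)} "
          f"({time.time()-t0:.0f} s)")
    return fit.x


def stage_hf(myo, x_healthy):
    t0 = time.time()

    def residuals(x):
        dil, slope, vol = x
        model = _healthy_model(x_healthy, myo)
        circ, lv, rv, cl, cr = apply_heart_failure(
            model.circ, model.lv, model.rv, myo, myo,
            lv_dilation_ml=dil, passive_slope_scale=slope,
            extra_volume_ml=vol)
        m = CoupledHeart(circ, lv, rv, cell_lv=cl, cell_rv=cr)
        h = m.simulate(cycles=4, dt=0.05)
        mlv = pv_metrics(h, "lv")
        return [
            (mlv["EDV"] - HF_TARGETS["EDV_lv"]) / HF_TARGETS["EDV_lv"],
            (mlv["EF"] - HF_TARGETS["EF_lv"]) / HF_TARGETS["EF_lv"],
            (mlv["P_max"] - HF_TARGETS["P_lv_max"]) / HF_TARGETS["P_lv_max"],
        ]

    fit = least_squares(residuals, [130.0, 0.5, 400.0],
                        bounds=([40.0, 0.2, 0.0], [260.0, 1.0, 1200.0]),
                        diff_step=0.1, xtol=1e-4, ftol=1e-4, max_nfev=40)
    print(f"[hf] dilation = {fit.x[0]:.1f} ml, slope scale = {fit.x[1]:.3f}, "
          f"extra volume = {fit.x[2]:.0f} ml; residuals = "
          f"{np.round(fit.fun, 4)} ({time.time()-t0:.0f} s)")
    return fit.x


def _hf_model(myo, x_healthy, x_hf, pump_params=None, schedule=None):
    model = _healthy_model(x_healthy, myo)
    circ, lv, rv, cl, cr = apply_heart_failure(
        model.circ, model.lv, model.rv, myo, myo,
        lv_dilation_ml=x_hf[0], passive_slope_scale=x_hf[1],
        extra_volume_ml=x_hf[2])
    m = CoupledHeart(circ, lv, rv, cell_lv=cl, cell_rv=cr)
    if pump_params is not None:
        m = attach_pump(m, pump_params, schedule)
    return m


def stage_pump(myo, x_healthy, x_hf):
    t0 = time.time()

    def run(pp):
        period = 60000.0 / 80.0
        sched = ramp_schedule(2100.0, 3150.0,
                              ramp_start_ms=3 * period + period / 2.0)
        m = _hf_model(myo, x_healthy, x_hf, pp, sched)
        h = m.simulate(cycles=7, dt=0.05)
        t = h["t"]
        m2100 = (t >= 2 * period) & (t <= 3 * period)   # 3rd cycle at 2,100
        m3150 = (t >= 5 * period) & (t <= 6 * period)   # settled at 3,150
        q1, q2 = h["Q_pump"][m2100], h["Q_pump"][m3150]
        return np.array([q1.min(), q1.max(), q2.min()])

    tg = np.array([PUMP_TARGETS["Q_base_2100"], PUMP_TARGETS["Q_peak_2100"],
                   PUMP_TARGETS["Q_base_3150"]])

    def residuals(x):
        g_p, f_p, k_r = x
        pp = PumpParams(g_p=g_p, f_p=-abs(f_p), k_r=k_r)
        return (run(pp) - tg) / tg

    fit = least_squares(residuals, [1.731e-3, 0.30, 0.10],
                        bounds=([8e-4, 0.02, 0.01], [4e-3, 2.0, 1.0]),
                        diff_step=0.08, xtol=1e-4, ftol=1e-4, max_nfev=40)
    g_p, f_p, k_r = fit.x
    print(f"[pump] g_p = {g_p:.5g}, f_p = {-abs(f_p):.5g}, k_r = {k_r:.4f}; "
          f"residuals = {np.round(fit.fun, 4)} ({time.time()-t0:.0f} s)")
    return PumpParams(g_p=g_p, f_p=-abs(f_p), k_r=k_r)


def stage_warmup(myo, x_healthy):
    t0 = time.time()
    model = _healthy_model(x_healthy, myo)
    h = model.simulate(cycles=10, dt=0.05)
    y = h["final_state"]
    i0 = model.n_cell
    comp = dict(zip(("sa", "sv", "pa", "pv", "la", "ra"), y[i0:i0 + 6]))
    print(f"[warmup] steady compartment volumes: "
          f"{ {k: round(v, 1) for k, v in comp.items()} } "
          f"({time.time()-t0:.0f} s)")
    return comp


def main():
    myo = stage_cell()
    sigma_f, purk = stage_tissue(myo)
    x_healthy = _load_checkpoint("x_healthy")
    if x_healthy is None:
        x_healthy = stage_healthy(myo)
        _checkpoint("x_healthy", list(x_healthy))
    x_hf = _load_checkpoint("x_hf")
    if x_hf is None:
        x_hf = stage_hf(myo, x_healthy)
        _checkpoint("x_hf", list(x_hf))
    pump_x = _load_checkpoint("pump")
    if pump_x is None:
        pump = stage_pump(myo, x_healthy, x_hf)
        _checkpoint("pump", {k: v for k, v in pump.__dict__.items()})
    else:
        pump = PumpParams(**pump_x)
    warm = _load_checkpoint("warm")
    if warm is None:
        warm = stage_warmup(myo, x_healthy)
        _checkpoint("warm", warm)

    k_lv, k_rv, v_sv, v_pv, r_sys, c_sa, r_pul, c_pa = x_healthy
    payload = {
        "cell": {
            "myocardial": {k: v for k, v in myo.to_dict().items()},
            "purkinje": {k: v for k, v in purk.params.to_dict().items()},
            "achieved": {
                "cv_ratio": float(purk.cv_ratio),
                "upstroke_ratio_clamped": float(purk.upstroke_ratio_clamped),
                "upstroke_ratio_cable": float(purk.upstroke_ratio_cable),
                "cv_myocardial_cm_ms": float(purk.cv_myocardial),
                "cv_purkinje_cm_ms": float(purk.cv_purkinje),
            },
        },
        "tissue": {
            "sigma_f": float(sigma_f),
            "sigma_s": float(sigma_f / 2.0),
            "sigma_n": float(sigma_f / 4.0),
            "cv_target_cm_ms": 0.06,
        },
        "circulation": {
            "R_sys": float(r_sys), "C_sa": float(c_sa),
            "R_pul": float(r_pul), "C_pa": float(c_pa),
            "V0_sv": float(v_sv), "V0_pv": float(v_pv),
            "init_volumes": {k: float(v) for k, v in warm.items()},
        },
        "chambers": {
            "lv": {"V0": 15.0, "c1": 0.79, "c2": 0.02,
                   "k_act": float(k_lv), "V_inf": HEALTHY_TARGETS["EDV_lv"]},
            "rv": {"V0": 10.0, "c1": 0.65, "c2": 0.015,
                   "k_act": float(k_rv), "V_inf": HEALTHY_TARGETS["EDV_rv"]},
        },
        "heart_failure": {
            "k_ta_scale": 0.5,
            "heart_rate": 80.0,
            "lv_dilation_ml": float(x_hf[0]),
            "passive_slope_scale": float(x_hf[1]),
            "extra_volume_ml": float(x_hf[2]),
            "edv_target": HF_TARGETS["EDV_lv"],
        },
        "pump": {k: v for k, v in pump.__dict__.items()},
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as f:
        yaml.safe_dump(_plain(payload), f, sort_keys=False)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
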