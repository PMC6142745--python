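"""Rotary blood pump (LVAD) model, speed controller and suction analytics.

Three coupled ODEs represent the pump: the motor winding equation (voltage
balance between drive, back-EMF and ohmic/inductive drops), the
electromagnetic torque transfer (T_e = 3 k_e I against impeller inertia and
hydraulic load torque), and the inlet-flow equation driven by the pump head
minus the LV-to-aorta pressure difference and flow-proportional inlet/outlet
losses:

    L dI/dt     = V_pump + 2 k_e w - R_pump I        (published sign; see below)
    J dw/dt     = 3 k_e I - (a_p Q^2 w + b_p Q w^2 + c_p w + d_p w^3)
    L_io dQ/dt  = dP - (P_as - P_lv) - (R_in + R_out) Q,  R_in+R_out = k_r |Q|
    dP          = e_p + f_p Q^3 + g_p w^2
    V_pump      = k_pump (w - w_set),   k_pump < 0 so a speed deficit raises drive

The winding equation keeps the published sign of the back-EMF term (it enters
on the drive side), which yields the steady state I = 2 k_e w / R_pump at
V_pump = 0; the conventional opposing sign is available via
``literal_emf_sign=False``.  Units: w rad/s, I A, Q L/min, pressures mmHg;
the right-hand sides are returned per millisecond for the coupled
integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .circulation import CoupledHeart

__all__ = [
    "PumpParams",
    "PumpState",
    "PumpModel",
    "controller_voltage",
    "pump_dp",
    "pump_rhs",
    "attach_pump",
    "speed_protocol",
    "ramp_schedule",
    "suction_metrics",
    "RPM_TO_RADS",
]

RPM_TO_RADS = 2.0 * math.pi / 60.0


@dataclass
class PumpParams:
    """Rotary-pump constants.

    Defaults are derived from the published operating points of a small
    centrifugal assist pump (2.2 -> 6.2 L/min over a cardiac cycle at
    2,100 RPM; 7 L/min baseline at 3,150 RPM) via steady-state pump algebra;
    all config-exposed.
    """

    k_e: float = 0.025        # V s/rad (= N m/A)
    R_pump: float = 1.0       # Ohm
    L: float = 0.01           # H
    J: float = 1e-4           # kg m^2
    a_p: float = 1e-6         # N m per (L/min)^2 (rad/s)
    b_p: float = 3e-8         # N m per (L/min) (rad/s)^2
    c_p: float = 1e-4         # N m per rad/s
    d_p: float = 5e-10        # N m per (rad/s)^3
    e_p: float = 0.0          # mmHg
    f_p: float = -0.30        # mmHg per (L/min)^3
    g_p: float = 1.731e-3     # mmHg per (rad/s)^2
    L_io: float = 0.1         # mmHg per (L/min/s), inlet+outlet inertance
    k_r: float = 0.10         # mmHg per (L/min)^2, flow-proportional loss
    R_cannula: float = 0.5    # mmHg per (L/min), linear cannula loss
    k_pump: float = -20.0     # V s/rad controller gain (negative: deficit
                              # raises drive)
    omega_set_rpm: float = 2100.0
    literal_emf_sign: bool = True

    def __post_init__(self):
        for name in ("R_pump", "L", "J"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_r < 0:
            raise ValueError("k_r must be nonnegative")
        if self.k_pump == 0:
            raise ValueError("controller gain must be nonzero")

    def with_(self, **kw) -> "PumpParams":
        return replace(self, **kw)

    @property
    def omega_set(self) -> float:
        return self.omega_set_rpm * RPM_TO_RADS


@dataclass
class PumpState:
    """Pump speed (rad/s), motor current (A), flow (L/min; may be negative:
    backflow through the pump is allowed)."""

    omega: float
    I: float
    Q: float

    def __post_init__(self):
        if self.omega < 0:
            raise ValueError("pump speed must be nonnegative")


def controller_voltage(omega: float, params: PumpParams,
                       omega_set: float | None = None) -> float:
    """Proportional speed controller V_pump = k_pump (w - w_set)."""
    ws = params.omega_set if omega_set is None else omega_set
    return params.k_pump * (omega - ws)


def pump_dp(Q: float, omega: float, params: PumpParams) -> float:
    """Pump pressure head dP = e_p + f_p Q^3 + g_p w^2 (mmHg)."""
    return params.e_p + params.f_p * Q ** 3 + params.g_p * omega ** 2


def pump_rhs(state: PumpState, P_as: float, P_lv_cannula: float,
             params: PumpParams, omega_set: float | None = None) -> tuple:
    """d(omega, I, Q)/dt in per-second units (motor/hydraulic equations)."""
    w, I, Q = state.omega, state.I, state.Q
    V = controller_voltage(w, params, omega_set)
    emf = 2.0 * params.k_e * w
    if params.literal_emf_sign:
        dI = (V + emf - params.R_pump * I) / params.L
    else:
        dI = (V - emf - params.R_pump * I) / params.L
    torque_load = (params.a_p * Q * Q * w + params.b_p * Q * w * w
                   + params.c_p * w + params.d_p * w ** 3)
    dw = (3.0 * params.k_e * I - torque_load) / params.J
    dp = pump_dp(Q, w, params)
    loss = (params.k_r * abs(Q) + params.R_cannula) * Q
    dQ = (dp - (P_as - P_lv_cannula) - loss) / params.L_io
    return dw, dI, dQ


class PumpModel:
    """Adapter binding PumpParams to the coupled-heart integrator
    (per-millisecond derivatives, initial state at the set point)."""

    def __init__(self, params: PumpParams):
        self.params = params

    def initial_state(self) -> tuple:
        """Controller/motor equilibrium at zero flow: speed near the set
        point with the current balancing the hydraulic load torque (the
        naive I = 2 k_e w/R would start ~25x over the load-balancing
        current and kick a large speed transient)."""
        p = self.params

        def residual(w):
            torque = (p.c_p * w + p.d_p * w ** 3)      # Q = 0
            I_torque = torque / (3.0 * p.k_e)
            V = controller_voltage(w, p)
            emf = 2.0 * p.k_e * w if p.literal_emf_sign else -2.0 * p.k_e * w
            I_winding = (V + emf) / p.R_pump
            return I_winding - I_torque

        w = brentq(residual, 0.5 * p.omega_set, 1.5 * p.omega_set,
                   xtol=1e-10)
        current = (p.c_p * w + p.d_p * w ** 3) / (3.0 * p.k_e)
        return (w, current, 0.0)

    def steady_current(self, omega: float) -> float:
        """Winding-equation equilibrium at V_pump = 0: I = 2 k_e w / R."""
        return 2.0 * self.params.k_e * omega / self.params.R_pump

    def steady_flow(self, omega: float, head: float) -> float:
        """Settled flow: root of dP(Q, w) - head - losses(Q) = 0."""
        p = self.params

        def f(Q):
            return (pump_dp(Q, omega, p) - head
                    - (p.k_r * abs(Q) + p.R_cannula) * Q)

        return brentq(f, -20.0, 40.0, xtol=1e-10)

    def dp(self, Q: float, omega: float) -> float:
        return pump_dp(Q, omega, self.params)

    def derivs(self, omega: float, current: float, Q: float, P_as: float,
               P_lv: float, omega_set: float) -> tuple:
        dw, dI, dQ = pump_rhs(PumpState(max(omega, 0.0), current, Q),
                              P_as, P_lv, self.params, omega_set)
        ms = 1e-3
        return (dw * ms, dI * ms, dQ * ms)


def attach_pump(model: CoupledHeart, pump_params: PumpParams,
                speed_setpoint=None) -> CoupledHeart:
    """Couple a pump into an existing heart model: the pump drains the LV
    chamber and feeds the systemic arterial compartment; the cannula-side
    pressure is the LV chamber pressure (single-pressure surrogate).

    ``speed_setpoint``: constant RPM, a schedule list [(t_ms, RPM), ...] or
    a callable t -> rad/s; defaults to the params' constant set speed.
    """
    if speed_setpoint is None:
        setpoint = speed_protocol([(0.0, pump_params.omega_set_rpm)])
    elif callable(speed_setpoint):
        setpoint = speed_setpoint
    elif np.isscalar(speed_setpoint):
        setpoint = speed_protocol([(0.0, float(speed_setpoint))])
    else:
        setpoint = speed_protocol(speed_setpoint)
    return CoupledHeart(
        circ=model.circ, lv=model.lv, rv=model.rv,
        cell_lv=model.cell_lv, cell_rv=model.cell_rv,
        mode=model.mode, ta_drive_lv=model.ta_drive_lv,
        ta_drive_rv=model.ta_drive_rv,
        stim_amplitude=model.stim_amplitude,
        stim_duration=model.stim_duration,
        pump=PumpModel(pump_params),
        pump_speed_setpoint=setpoint,
    )


def speed_protocol(schedule: list):
    """Piecewise-linear speed set-point w_set(t) from (time ms, RPM)
    breakpoints; constant extrapolation outside.  Returns a callable giving
    rad/s.  Non-monotone breakpoint times are an error."""
    pts = [(float(t), float(rpm)) for t, rpm in schedule]
    times = [t for t, _ in pts]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("schedule times must be strictly increasing")
    t_arr = np.array(times)
    rpm_arr = np.array([r for _, r in pts])

    def omega_set(t: float) -> float:
        return float(np.interp(t, t_arr, rpm_arr)) * RPM_TO_RADS

    return omega_set


def ramp_schedule(base_rpm: float = 2100.0, target_rpm: float = 3150.0,
                  ramp_start_ms: float = 0.0,
                  ramp_duration_ms: float = 300.0) -> list:
    """Linear speed ramp: hold base, ramp over ``ramp_duration_ms``, hold
    target (the published protocol ramps to 150% of 2,100 = 3,150 RPM over
    300 ms after half a systolic cycle)."""
    return [(0.0, base_rpm), (ramp_start_ms, base_rpm),
            (ramp_start_ms + ramp_duration_ms, target_rpm)]


def suction_metrics(history: dict, edv_decline_frac: float = 0.10,
                    n_consecutive: int = 2) -> dict:
    """Per-cycle suction report for a pump-supported run.

    Per cycle: minimum LV pressure, EDV, pump-flow pulsatility (max - min)
    and the fraction of the cycle spent at negative LV pressure.  Suction is
    flagged when EDV declines by at least ``edv_decline_frac`` per cycle for
    ``n_consecutive`` consecutive cycles AND the minimum LV pressure is
    negative in the last of those cycles.
    """
    from .circulation import cycle_metrics

    cycles = cycle_metrics(history, "lv")
    if len(cycles) < 2:
        raise ValueError("need at least 2 cycles for suction analytics")
    t = history["t"]
    period = history["period_ms"]
    report = []
    for k, c in enumerate(cycles):
        m = (t >= t[0] + k * period) & (t <= t[0] + (k + 1) * period + 1e-9)
        p_lv = history["P_lv"][m]
        entry = {
            "cycle": k,
            "EDV": c["EDV"],
            "P_lv_min": float(p_lv.min()),
            "neg_pressure_fraction": float(np.mean(p_lv < 0.0)),
        }
        if "Q_pump" in history:
            entry["pump_pulsatility"] = c.get("pulsatility", 0.0)
        report.append(entry)

    declines = []
    for prev, cur in zip(report[:-1], report[1:]):
        declines.append((prev["EDV"] - cur["EDV"]) >= edv_decline_frac
                        * max(prev["EDV"], 1e-9))
    flag = False
    for k in range(len(declines) - n_consecutive + 1):
        window = declines[k:k + n_consecutive]
        if all(window) and report[k + n_consecutive]["P_lv_min"] < 0.0:
            flag = True
            break
    return {"cycles": report, "suction": flag}
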