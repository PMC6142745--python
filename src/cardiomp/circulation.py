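"""Closed-loop lumped circulation with elastance chamber surrogates.

The circuit follows the classic closed-loop layout: each side has an
arterial and a venous RC compartment with unstressed volumes, the atria are
passive compliances, and diode-resistor valves feed two ventricular
chambers.  The resolved-wall ventricle is replaced by a time-varying
elastance surrogate driven by active stress:

    P(V, Ta) = c1 (exp(c2 (V - V0)) - 1) + k_act * <Ta> * (V - V0)

with <Ta> the tissue-averaged active stress (kPa) -- in 0D mode the cell
model's own T_a, in staged mode a precomputed spatial mean from a tissue
run.  The electro -> mechanics -> hemodynamics causal chain is preserved:
activation timing shapes <Ta>(t), which shapes pressures and flows.

Units: volumes ml, pressures mmHg, resistances mmHg s ml^-1, compliances
ml mmHg^-1, time ms internally (flows converted from ml/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field as dfield

import numpy as np

from .cell import CellParams, StimulusProtocol

__all__ = [
    "CircParams",
    "ChamberSurrogate",
    "CircState",
    "chamber_pressure",
    "valve_flow",
    "fill_to_edv",
    "circulation_rhs",
    "CoupledHeart",
    "apply_heart_failure",
    "pv_metrics",
    "cycle_metrics",
]

_COMPARTMENTS = ("sa", "sv", "pa", "pv", "la", "ra")


@dataclass
class CircParams:
    """Windkessel circuit constants (systemic/pulmonary arteries and veins,
    passive atria) plus valve and perfusion resistances."""

    heart_rate: float = 60.0      # bpm
    # resistances, mmHg s/ml
    R_mi: float = 0.005
    R_ao: float = 0.010
    R_tri: float = 0.005
    R_pa: float = 0.010
    R_sys: float = 1.20
    R_pul: float = 0.15
    R_sv: float = 0.030           # systemic veins -> right atrium
    R_pv: float = 0.030           # pulmonary veins -> left atrium
    # compliances, ml/mmHg
    C_sa: float = 1.4
    C_sv: float = 80.0
    C_pa: float = 4.5
    C_pv: float = 10.0
    C_la: float = 10.0
    C_ra: float = 12.0
    # unstressed volumes, ml
    Vu_sa: float = 500.0
    Vu_sv: float = 2500.0
    Vu_pa: float = 90.0
    Vu_pv: float = 120.0
    Vu_la: float = 10.0
    Vu_ra: float = 10.0
    # initial compartment volumes (near steady state), ml
    V0_sa: float = 640.0
    V0_sv: float = 2900.0
    V0_pa: float = 180.0
    V0_pv: float = 200.0
    V0_la: float = 90.0
    V0_ra: float = 60.0
    valve_smoothing: float = 0.0  # mmHg; 0 = ideal diode

    def __post_init__(self):
        for name in ("R_mi", "R_ao", "R_tri", "R_pa", "R_sys", "R_pul",
                     "R_sv", "R_pv", "C_sa", "C_sv", "C_pa", "C_pv",
                     "C_la", "C_ra"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kw) -> "CircParams":
        return replace(self, **kw)

    @property
    def period_ms(self) -> float:
        return 60000.0 / self.heart_rate

    def pressure(self, comp: str, V: float) -> float:
        return (V - getattr(self, f"Vu_{comp}")) / getattr(self, f"C_{comp}")


@dataclass
class ChamberSurrogate:
    """Elastance closure for one ventricle."""

    V0: float = 60.0        # ml unloaded volume
    c1: float = 1.3         # mmHg passive EDPVR scale
    c2: float = 0.025       # 1/ml passive EDPVR exponent
    k_act: float = 0.28     # mmHg kPa^-1 ml^-1 activation gain
    V_inf: float = 148.0    # ml filling target (end-diastolic volume)

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0 or self.k_act <= 0:
            raise ValueError("surrogate coefficients must be positive")

    def with_(self, **kw) -> "ChamberSurrogate":
        return replace(self, **kw)


@dataclass
class CircState:
    """Compartment + chamber volumes (ml) and derived flows (ml/s)."""

    V: dict
    V_lv: float
    V_rv: float
    Q_mi: float = 0.0
    Q_ao: float = 0.0
    Q_tri: float = 0.0
    Q_pa: float = 0.0

    def total_volume(self) -> float:
        return sum(self.V.values()) + self.V_lv + self.V_rv


def chamber_pressure(V: float, mean_Ta: float, surrogate: ChamberSurrogate) -> float:
    """Ventricular pressure (mmHg) from volume and mean active stress."""
    s = surrogate
    p_pas = s.c1 * (math.exp(s.c2 * (V - s.V0)) - 1.0)
    return p_pas + s.k_act * mean_Ta * (V - s.V0)


def valve_flow(P_up: float, P_down: float, R: float,
               smoothing: float = 0.0) -> float:
    """Ideal-diode valve flow (ml/s); optional softplus smoothing (mmHg)
    for stiff-solver robustness."""
    if R <= 0:
        raise ValueError("valve resistance must be positive")
    dp = P_up - P_down
    if smoothing > 0.0:
        # softplus: smooth, positive, -> dp for dp >> smoothing
        x = dp / smoothing
        if x > 30.0:
            dp_eff = dp
        else:
            dp_eff = smoothing * math.log1p(math.exp(x))
        return dp_eff / R
    return dp / R if dp > 0.0 else 0.0


def fill_to_edv(surrogate: ChamberSurrogate, k_flow: float = 200.0,
                V_start: float | None = None, tol: float = 1e-3,
                max_time: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Pre-inflation of a decoupled chamber: dV/dt = -k_flow (V - V_inf).

    ``k_flow`` is a pure rate constant (per ms; the published 200,000 s^-1),
    giving a sub-millisecond inflation time constant.  Integrates with an
    implicit stiff solver until |V - V_inf| < tol * V_inf and returns the
    (t, V) trajectory.
    """
    from scipy.integrate import solve_ivp

    V_inf = surrogate.V_inf
    V_start = surrogate.V0 if V_start is None else V_start

    def rhs(t, y):
        return [-k_flow * (y[0] - V_inf)]

    def done(t, y):
        return abs(y[0] - V_inf) - tol * V_inf

    done.terminal = True
    sol = solve_ivp(rhs, (0.0, max_time), [V_start], method="Radau",
                    events=done, rtol=1e-10, atol=1e-12, dense_output=True)
    if not sol.t_events[0].size and abs(sol.y[0, -1] - V_inf) > tol * V_inf:
        raise RuntimeError(
            f"inflation did not converge within {max_time} ms "
            f"(V = {sol.y[0, -1]:.2f} vs target {V_inf:.2f} ml)")
    t = np.linspace(0.0, sol.t[-1], 200)
    return t, sol.sol(t)[0]


def _flows(params: CircParams, P: dict, P_lv: float, P_rv: float) -> dict:
    sm = params.valve_smoothing
    return {
        "Q_mi": valve_flow(P["la"], P_lv, params.R_mi, sm),
        "Q_ao": valve_flow(P_lv, P["sa"], params.R_ao, sm),
        "Q_tri": valve_flow(P["ra"], P_rv, params.R_tri, sm),
        "Q_pa": valve_flow(P_rv, P["pa"], params.R_pa, sm),
        "Q_sys": (P["sa"] - P["sv"]) / params.R_sys,
        "Q_sv_ra": (P["sv"] - P["ra"]) / params.R_sv,
        "Q_pul": (P["pa"] - P["pv"]) / params.R_pul,
        "Q_pv_la": (P["pv"] - P["la"]) / params.R_pv,
    }


def circulation_rhs(state: CircState, params: CircParams,
                    lv: ChamberSurrogate, rv: ChamberSurrogate,
                    mean_Ta_lv: float, mean_Ta_rv: float,
                    pump_flow_mls: float = 0.0) -> dict:
    """Volume balance (ml/ms) for every compartment and chamber.

    ``pump_flow_mls`` (ml/s) drains the LV into the systemic arteries when
    an assist device is attached.
    """
    P = {c: params.pressure(c, state.V[c]) for c in _COMPARTMENTS}
    P_lv = chamber_pressure(state.V_lv, mean_Ta_lv, lv)
    P_rv = chamber_pressure(state.V_rv, mean_Ta_rv, rv)
    q = _flows(params, P, P_lv, P_rv)
    for v in state.V.values():
        if v < 0:
            raise RuntimeError("negative compartment volume: circulation "
                               "state is unphysical")
    ms = 1e-3  # flows are ml/s, time axis is ms
    return {
        "sa": (q["Q_ao"] - q["Q_sys"] + pump_flow_mls) * ms,
        "sv": (q["Q_sys"] - q["Q_sv_ra"]) * ms,
        "pa": (q["Q_pa"] - q["Q_pul"]) * ms,
        "pv": (q["Q_pul"] - q["Q_pv_la"]) * ms,
        "la": (q["Q_pv_la"] - q["Q_mi"]) * ms,
        "ra": (q["Q_sv_ra"] - q["Q_tri"]) * ms,
        "lv": (q["Q_mi"] - q["Q_ao"] - pump_flow_mls) * ms,
        "rv": (q["Q_tri"] - q["Q_pa"]) * ms,
        "flows": q,
        "P": {**P, "lv": P_lv, "rv": P_rv},
    }


# ---------------------------------------------------------------------------
# monolithic coupled model (cells + circulation [+ pump])


class CoupledHeart:
    """Cell electromechanics + closed-loop circulation, one fixed-step RK4
    integrator (optionally with a rotary pump attached).

    Modes: ``"0d"`` (each ventricle's <Ta> is its own space-clamped cell's
    T_a, integrated monolithically) or ``"staged"`` (precomputed <Ta>(t)
    callables from a tissue run drive the chambers; cell states drop out of
    the state vector).
    """

    def __init__(
        self,
        circ: CircParams,
        lv: ChamberSurrogate,
        rv: ChamberSurrogate,
        cell_lv: CellParams | None = None,
        cell_rv: CellParams | None = None,
        mode: str = "0d",
        ta_drive_lv=None,
        ta_drive_rv=None,
        stim_amplitude: float = 12.0,
        stim_duration: float = 2.0,
        pump=None,
        pump_speed_setpoint=None,
    ):
        if mode not in ("0d", "staged"):
            raise ValueError("mode must be '0d' or 'staged'")
        if mode == "0d" and (cell_lv is None or cell_rv is None):
            raise ValueError("0d mode needs both cell parameter sets")
        if mode == "staged" and (ta_drive_lv is None or ta_drive_rv is None):
            raise ValueError("staged mode needs <Ta>(t) drives")
        self.circ = circ
        self.lv, self.rv = lv, rv
        self.cell_lv, self.cell_rv = cell_lv, cell_rv
        self.mode = mode
        self.ta_drive_lv, self.ta_drive_rv = ta_drive_lv, ta_drive_rv
        self.stim_amplitude = stim_amplitude
        self.stim_duration = stim_duration
        self.pump = pump
        self.pump_speed_setpoint = pump_speed_setpoint
        self.n_cell = 6 if mode == "0d" else 0
        self.n_circ = 8
        self.n_pump = 3 if pump is not None else 0

    # -- state layout ------------------------------------------------------
    def initial_state(self, fill: bool = True) -> list:
        c = self.circ
        y = []
        if self.mode == "0d":
            y += [self.cell_lv.B, 0.0, 0.0, self.cell_rv.B, 0.0, 0.0]
        y += [c.V0_sa, c.V0_sv, c.V0_pa, c.V0_pv, c.V0_la, c.V0_ra]
        if fill:
            y += [self.lv.V_inf, self.rv.V_inf]
        else:
            y += [self.lv.V0, self.rv.V0]
        if self.pump is not None:
            y += list(self.pump.initial_state())
        return y

    def _cell_rhs(self, V, R, Ta, p: CellParams, stim: float):
        u = (V - p.B) / p.A
        dv = V - p.B
        iion = (p.k1 * p.k2 * dv * (u - p.a) * (u - 1.0) + p.k2 * R * dv)
        dV = -iion / p.Cm + stim
        rate = p.eps0 + p.mu1 * R / (u + p.mu2)
        dR = rate * (-R - p.k1 * u * (u - p.a - 1.0))
        g = math.exp(-math.exp(-p.xi * (V - p.V_threshold)))
        eps = p.eps0_act + (p.epsinf_act - p.eps0_act) * g
        upos = u if u > 0.0 else 0.0
        dTa = eps * (p.k_Ta * upos - Ta)
        return dV, dR, dTa

    def rhs(self, t: float, y: list) -> list:
        period = self.circ.period_ms
        stim = (self.stim_amplitude
                if (t % period) < self.stim_duration else 0.0)
        out = [0.0] * len(y)
        if self.mode == "0d":
            out[0:3] = self._cell_rhs(y[0], y[1], y[2], self.cell_lv, stim)
            out[3:6] = self._cell_rhs(y[3], y[4], y[5], self.cell_rv, stim)
            ta_lv, ta_rv = y[2], y[5]
        else:
            ta_lv = float(self.ta_drive_lv(t))
            ta_rv = float(self.ta_drive_rv(t))

        i0 = self.n_cell
        V = dict(zip(_COMPARTMENTS, y[i0:i0 + 6]))
        V_lv, V_rv = y[i0 + 6], y[i0 + 7]
        state = CircState(V=V, V_lv=V_lv, V_rv=V_rv)

        pump_flow_mls = 0.0
        if self.pump is not None:
            omega, current, q_pump = y[i0 + 8:i0 + 11]
            P_sa = self.circ.pressure("sa", V["sa"])
            P_lv = chamber_pressure(V_lv, ta_lv, self.lv)
            omega_set = self.pump_speed_setpoint(t)
            d_pump = self.pump.derivs(omega, current, q_pump,
                                      P_sa, P_lv, omega_set)
            out[i0 + 8:i0 + 11] = d_pump
            pump_flow_mls = q_pump * (1000.0 / 60.0)  # L/min -> ml/s

        d = circulation_rhs(state, self.circ, self.lv, self.rv,
                            ta_lv, ta_rv, pump_flow_mls)
        out[i0:i0 + 6] = [d[c] for c in _COMPARTMENTS]
        out[i0 + 6], out[i0 + 7] = d["lv"], d["rv"]
        self._last_aux = (d["flows"], d["P"])
        return out

    # -- integration -------------------------------------------------------
    def simulate(self, cycles: float, dt: float = 0.02, dt_out: float = 2.0,
                 y0: list | None = None, t0: float = 0.0) -> dict:
        """Fixed-step RK4 over ``cycles`` cardiac cycles; history resampled
        at ``dt_out`` (default 2 ms).  Returns a dict of 1D arrays."""
        period = self.circ.period_ms
        duration = cycles * period
        nsteps = int(round(duration / dt))
        y = list(self.initial_state()) if y0 is None else list(y0)

        cols = ["t", "P_lv", "P_rv", "P_ao", "P_pa", "V_lv", "V_rv",
                "Q_mi", "Q_ao", "Q_tri", "Q_pa", "Ta_lv", "Ta_rv",
                "V_total"]
        if self.pump is not None:
            cols += ["omega", "omega_set", "I_pump", "Q_pump", "dP_pump"]
        rec = {c: [] for c in cols}

        def record(t, y):
            self.rhs(t, y)  # refresh aux
            flows, P = self._last_aux
            i0 = self.n_cell
            rec["t"].append(t)
            rec["P_lv"].append(P["lv"])
            rec["P_rv"].append(P["rv"])
            rec["P_ao"].append(P["sa"])
            rec["P_pa"].append(P["pa"])
            rec["V_lv"].append(y[i0 + 6])
            rec["V_rv"].append(y[i0 + 7])
            for qn in ("Q_mi", "Q_ao", "Q_tri", "Q_pa"):
                rec[qn].append(flows[qn])
            if self.mode == "0d":
                rec["Ta_lv"].append(y[2])
                rec["Ta_rv"].append(y[5])
            else:
                rec["Ta_lv"].append(float(self.ta_drive_lv(t)))
                rec["Ta_rv"].append(float(self.ta_drive_rv(t)))
            rec["V_total"].append(sum(y[i0:i0 + 8]))
            if self.pump is not None:
                omega, cur, q = y[i0 + 8:i0 + 11]
                rec["omega"].append(omega)
                rec["omega_set"].append(self.pump_speed_setpoint(t))
                rec["I_pump"].append(cur)
                rec["Q_pump"].append(q)
                rec["dP_pump"].append(self.pump.dp(q, omega))

        record(t0, y)
        next_out = t0 + dt_out
        t = t0
        for k in range(nsteps):
            k1 = self.rhs(t, y)
            y2 = [yi + 0.5 * dt * ki for yi, ki in zip(y, k1)]
            k2 = self.rhs(t + 0.5 * dt, y2)
            y3 = [yi + 0.5 * dt * ki for yi, ki in zip(y, k2)]
            k3 = self.rhs(t + 0.5 * dt, y3)
            y4 = [yi + dt * ki for yi, ki in zip(y, k3)]
            k4 = self.rhs(t + dt, y4)
            y = [yi + dt / 6.0 * (a + 2 * b + 2 * c_ + d_)
                 for yi, a, b, c_, d_ in zip(y, k1, k2, k3, k4)]
            t = t0 + (k + 1) * dt
            if t >= next_out - 1e-9:
                record(t, y)
                next_out += dt_out
        hist = {k: np.asarray(v) for k, v in rec.items()}
        hist["final_state"] = list(y)
        hist["period_ms"] = period
        return hist


def apply_heart_failure(circ: CircParams, lv: ChamberSurrogate,
                        rv: ChamberSurrogate, cell_lv: CellParams,
                        cell_rv: CellParams,
                        k_ta_scale: float = 0.5,
                        heart_rate: float = 80.0,
                        lv_dilation_ml: float = 95.0,
                        passive_slope_scale: float = 0.5,
                        edv_target: float = 299.0,
                        extra_volume_ml: float = 0.0):
    """Dilated-cardiomyopathy modifications: LV contraction strength halved
    (k_Ta x 0.5), heart rate raised to 80 bpm, LV dilated (V0 shifted and
    the passive EDPVR slope relaxed) and optional fluid retention
    (``extra_volume_ml`` added to the venous pool); scalings config-exposed.
    The RV is untouched."""
    circ_hf = circ.with_(heart_rate=heart_rate,
                         V0_sv=circ.V0_sv + extra_volume_ml)
    lv_hf = lv.with_(V0=lv.V0 + lv_dilation_ml,
                     c2=lv.c2 * passive_slope_scale,
                     V_inf=edv_target)
    cell_lv_hf = cell_lv.with_(k_Ta=cell_lv.k_Ta * k_ta_scale)
    return circ_hf, lv_hf, rv, cell_lv_hf, cell_rv


# ---------------------------------------------------------------------------
# metrics


def cycle_metrics(history: dict, chamber: str = "lv") -> list[dict]:
    """Per-cycle extrema: EDV/ESV/EF/SV, peak/min pressures, valve-flow
    integrals.  Cycles are delimited by the pacing period."""
    t = history["t"]
    period = history["period_ms"]
    Vkey, Pkey = f"V_{chamber}", f"P_{chamber}"
    out = []
    n_cycles = int(round((t[-1] - t[0]) / period))
    for k in range(n_cycles):
        m = (t >= t[0] + k * period) & (t <= t[0] + (k + 1) * period + 1e-9)
        if m.sum() < 5:
            continue
        V, P = history[Vkey][m], history[Pkey][m]
        edv, esv = float(V.max()), float(V.min())
        entry = {
            "cycle": k,
            "EDV": edv,
            "ESV": esv,
            "SV": edv - esv,
            "EF": 100.0 * (edv - esv) / edv if edv > 0 else 0.0,
            "P_max": float(P.max()),
            "P_min": float(P.min()),
        }
        dt_s = np.diff(t[m]) * 1e-3
        for qn in ("Q_ao", "Q_mi", "Q_pa", "Q_tri"):
            q = history[qn][m]
            entry[f"{qn}_int"] = float(np.sum(0.5 * (q[1:] + q[:-1]) * dt_s))
        if "Q_pump" in history:
            qp = history["Q_pump"][m]
            entry["Q_pump_min"] = float(qp.min())
            entry["Q_pump_max"] = float(qp.max())
            entry["pulsatility"] = float(qp.max() - qp.min())
        out.append(entry)
    return out


def pv_metrics(history: dict, chamber: str = "lv",
               cycle: int = -1) -> dict:
    """EDV, ESV, EF (%), SV and pressure extrema for one cycle (default the
    last complete one)."""
    cycles = cycle_metrics(history, chamber)
    if not cycles:
        raise ValueError("history contains no complete cycle")
    return cycles[cycle]
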