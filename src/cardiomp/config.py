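"""Shipped calibrated defaults and model builders.

``data/default_params.yaml`` is the versioned output of
``scripts/calibrate_defaults.py``; every numeric constant used by the
standard protocols resolves through here (no hidden literals), so the full
runtime configuration can be audited from one snapshot.
"""

from __future__ import annotations

import copy
from functools import lru_cache
from importlib import resources

import yaml

from .cell import CellParams, AP_ENDO, AP_EPI
from .circulation import (CircParams, ChamberSurrogate, CoupledHeart,
                          apply_heart_failure)
from .lvad import PumpParams

__all__ = [
    "load_defaults",
    "myocardial_params",
    "purkinje_params",
    "circ_params",
    "chamber",
    "pump_params",
    "standard_model",
    "heart_failure_model",
    "resolved_config",
]


@lru_cache(maxsize=1)
def _raw() -> dict:
    with resources.files("cardiomp.data").joinpath(
            "default_params.yaml").open() as f:
        return yaml.safe_load(f)


def load_defaults() -> dict:
    """Deep copy of the resolved default-parameter snapshot."""
    return copy.deepcopy(_raw())


def myocardial_params(kind: str = "epi",
                      heart_failure: bool = False) -> CellParams:
    """Calibrated myocardial cell parameters; ``kind`` selects the
    transmural excitation threshold ('epi', 'endo' or a float)."""
    d = dict(_raw()["cell"]["myocardial"])
    if kind == "epi":
        d["a"] = AP_EPI
    elif kind == "endo":
        d["a"] = AP_ENDO
    else:
        d["a"] = float(kind)
    p = CellParams(**d)
    if heart_failure:
        p = p.with_(k_Ta=p.k_Ta * _raw()["heart_failure"]["k_ta_scale"])
    return p


def purkinje_params() -> CellParams:
    return CellParams(**_raw()["cell"]["purkinje"])


def circ_params(heart_failure: bool = False) -> CircParams:
    d = _raw()["circulation"]
    init = d["init_volumes"]
    circ = CircParams(
        R_sys=d["R_sys"], C_sa=d["C_sa"], R_pul=d["R_pul"], C_pa=d["C_pa"],
        V0_sa=init["sa"], V0_sv=init["sv"], V0_pa=init["pa"],
        V0_pv=init["pv"], V0_la=init["la"], V0_ra=init["ra"],
    )
    if heart_failure:
        hf = _raw()["heart_failure"]
        circ = circ.with_(heart_rate=hf["heart_rate"],
                          V0_sv=circ.V0_sv + hf["extra_volume_ml"])
    return circ


def chamber(side: str, heart_failure: bool = False) -> ChamberSurrogate:
    s = ChamberSurrogate(**_raw()["chambers"][side])
    if heart_failure and side == "lv":
        hf = _raw()["heart_failure"]
        s = s.with_(V0=s.V0 + hf["lv_dilation_ml"],
                    c2=s.c2 * hf["passive_slope_scale"],
                    V_inf=hf["edv_target"])
    return s


def pump_params(**overrides) -> PumpParams:
    d = dict(_raw()["pump"])
    d.update(overrides)
    return PumpParams(**d)


def standard_model(**kw) -> CoupledHeart:
    """Healthy 0D model at 60 bpm from the shipped calibration."""
    return CoupledHeart(circ_params(), chamber("lv"), chamber("rv"),
                        cell_lv=myocardial_params(),
                        cell_rv=myocardial_params(), **kw)


def heart_failure_model(**kw) -> CoupledHeart:
    """Dilated failing heart at 80 bpm (LV k_Ta halved, dilated, volume
    expanded) from the shipped calibration."""
    return CoupledHeart(circ_params(heart_failure=True),
                        chamber("lv", heart_failure=True), chamber("rv"),
                        cell_lv=myocardial_params(heart_failure=True),
                        cell_rv=myocardial_params(), **kw)


def resolved_config() -> dict:
    """The complete numeric configuration a run resolves to (audit trail)."""
    return load_defaults()
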