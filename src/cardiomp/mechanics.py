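"""Material-point myocardial mechanics.

Transverse-isotropic Holzapfel-Ogden strain energy with a volumetric
penalty,

    psi = a_i/(2 b_i) exp(b_i (I1_bar - 3))
        + a_f/(2 b_f) [exp(b_f (I4f - 1)^2) - 1]    (tension only, I4f > 1)
        + kappa (J - 1) ln(J)^2

where I1_bar is the first invariant of the isochoric right Cauchy-Green
tensor (J^(-2/3) C) and I4f = F_hat . (C F_hat) the squared fiber stretch.
The passive 2nd Piola-Kirchhoff stress is the analytic derivative
S = 2 dpsi/dC; active stress T_a is added along the material triad with
fractions (1, 0.4, 0.4) in the fiber/sheet/normal directions (isotropic
points get T_a I).  Stresses in kPa, lengths dimensionless (stretches).

A cannula-contact penalty pressure and stress-strain loop analytics
(regional-work proxy) complete the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialParams",
    "ContactParams",
    "DeformationState",
    "strain_energy",
    "pk2_stress",
    "stress_strain_loop",
    "contact_pressure",
]


@dataclass
class MaterialParams:
    """Holzapfel-Ogden transverse-isotropic constants.

    Defaults follow the transverse-isotropic reductions fitted to myocardial
    biaxial data in the constitutive-modeling literature; all overridable.
    """

    a_i: float = 2.28       # kPa, isotropic exponential scale
    b_i: float = 9.726      # -, isotropic exponent
    a_f: float = 1.685      # kPa, fiber exponential scale
    b_f: float = 15.779     # -, fiber exponent
    kappa: float = 350.0    # kPa, bulk penalty
    active_cross_fraction: float = 0.4

    def __post_init__(self):
        for name in ("a_i", "b_i", "a_f", "b_f", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"modulus {name} must be positive")
        if not 0.0 <= self.active_cross_fraction <= 1.0:
            raise ValueError("active cross-fiber fraction must lie in [0, 1]")

    UNITS = {"a_i": "kPa", "b_i": "1", "a_f": "kPa", "b_f": "1",
             "kappa": "kPa", "active_cross_fraction": "1"}

    def to_yaml(self, path=None) -> str:
        import yaml
        from dataclasses import asdict

        payload = {k: {"value": v, "units": self.UNITS[k]}
                   for k, v in asdict(self).items()}
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path) -> "MaterialParams":
        import os
        import yaml

        text = text_or_path
        if os.path.exists(str(text_or_path)):
            with open(text_or_path) as f:
                text = f.read()
        payload = yaml.safe_load(text)
        return cls(**{k: v["value"] for k, v in payload.items()})


@dataclass
class ContactParams:
    """Cannula contact penalty: load per unit gap-reciprocal excess."""

    k_contact: float = 1e3   # load scale per m^-1 of excess
    G_limit: float = 150.0   # m^-1 threshold

    def __post_init__(self):
        if self.k_contact <= 0 or self.G_limit <= 0:
            raise ValueError("contact parameters must be positive")


class DeformationState:
    """Deformation gradient with derived kinematic quantities.

    Attributes: C = F^T F, J = det F, E = (C - I)/2, I1_bar (isochoric first
    invariant) and I4f = f . (C f) for a given fiber direction.
    """

    def __init__(self, F: np.ndarray):
        F = np.asarray(F, float)
        if F.shape != (3, 3):
            raise ValueError("F must be 3x3")
        self.F = F
        self.J = float(np.linalg.det(F))
        if self.J <= 0:
            raise ValueError(f"inverted configuration: det F = {self.J:.3g} <= 0")
        self.C = F.T @ F
        self.E = 0.5 * (self.C - np.eye(3))
        self.I1 = float(np.trace(self.C))
        self.I1_bar = self.J ** (-2.0 / 3.0) * self.I1
        self.C_inv = np.linalg.inv(self.C)

    def I4(self, direction: np.ndarray) -> float:
        d = np.asarray(direction, float)
        return float(d @ (self.C @ d))


def _check_triad(triad) -> tuple:
    f, s, n = (np.asarray(v, float) for v in triad)
    M = np.column_stack([f, s, n])
    if not np.allclose(M.T @ M, np.eye(3), atol=1e-8):
        raise ValueError("material triad is not orthonormal")
    return f, s, n


def strain_energy(state: DeformationState, params: MaterialParams,
                  fiber: np.ndarray | None = None,
                  isotropic: bool = False) -> float:
    """Strain energy density (kPa).

    The fiber term engages only in tension (I4f > 1): compressed fibers do
    not contribute to passive stiffness.  Isotropic (apical) points carry
    only the isotropic and volumetric terms.
    """
    p = params
    psi = p.a_i / (2.0 * p.b_i) * np.exp(p.b_i * (state.I1_bar - 3.0))
    J = state.J
    psi += p.kappa * (J - 1.0) * np.log(J) ** 2
    if not isotropic:
        if fiber is None:
            raise ValueError("fiber direction required for anisotropic points")
        I4f = state.I4(fiber)
        if I4f > 1.0:
            psi += p.a_f / (2.0 * p.b_f) * (np.exp(p.b_f * (I4f - 1.0) ** 2) - 1.0)
    return float(psi)


def _passive_pk2(state: DeformationState, params: MaterialParams,
                 fiber: np.ndarray | None, isotropic: bool) -> np.ndarray:
    """Analytic S = 2 dpsi/dC."""
    p = params
    J, C_inv = state.J, state.C_inv
    I = np.eye(3)

    # isochoric-isotropic term: dI1_bar/dC = J^(-2/3) (I - I1/3 C^-1)
    scale = p.a_i * np.exp(p.b_i * (state.I1_bar - 3.0))
    S = scale * J ** (-2.0 / 3.0) * (I - state.I1 / 3.0 * C_inv)

    # volumetric: 2 dpsi/dC = psi'(J) J C^-1
    lnJ = np.log(J)
    dpsi_dJ = p.kappa * (lnJ ** 2 + 2.0 * (J - 1.0) * lnJ / J)
    S = S + dpsi_dJ * J * C_inv

    if not isotropic and fiber is not None:
        I4f = state.I4(fiber)
        if I4f > 1.0:
            g = 2.0 * p.a_f * (I4f - 1.0) * np.exp(p.b_f * (I4f - 1.0) ** 2)
            S = S + g * np.outer(fiber, fiber)
    return S


def pk2_stress(state: DeformationState, T_a: float, params: MaterialParams,
               triad=None, isotropic: bool = False) -> np.ndarray:
    """Total 2nd Piola-Kirchhoff stress (kPa): analytic passive part plus
    active stress along the material triad with fractions (1, 0.4, 0.4);
    isotropic points receive an isotropic active stress T_a I."""
    if T_a < 0:
        raise ValueError("active stress must be nonnegative")
    if isotropic:
        S = _passive_pk2(state, params, None, True)
        return S + T_a * np.eye(3)
    if triad is None:
        raise ValueError("material triad required for anisotropic points")
    f, s, n = _check_triad(triad)
    S = _passive_pk2(state, params, f, False)
    c = params.active_cross_fraction
    S = S + T_a * (np.outer(f, f) + c * np.outer(s, s) + c * np.outer(n, n))
    return S


def stress_strain_loop(stress_series, strain_series) -> dict:
    """Loop trace and signed (shoelace) area over one cycle of paired
    stress/strain samples -- a regional-work proxy (kPa).

    An open loop is closed with a straight segment and flagged with a
    warning.  Returns {'E': ..., 'S': ..., 'area': ...}.
    """
    S = np.asarray(stress_series, float).ravel()
    E = np.asarray(strain_series, float).ravel()
    if S.shape != E.shape:
        raise ValueError("stress and strain series must have equal length")
    if len(S) < 3:
        raise ValueError("need at least 3 samples for a loop")
    gap = np.hypot(S[0] - S[-1], E[0] - E[-1])
    steps = np.hypot(np.diff(S), np.diff(E))
    step_scale = max(float(np.median(steps)), 1e-30)
    if gap > 3.0 * step_scale:
        warnings.warn("open stress-strain loop: closing with a straight "
                      "segment", stacklevel=2)
    # shoelace on (E, S) pairs, implicit closure
    area = 0.5 * float(np.sum(E * np.roll(S, -1) - np.roll(E, -1) * S))
    return {"E": E, "S": S, "area": area}


def loop_to_csv(loop: dict, path, t_ms=None, component: str = "ff") -> None:
    """Write one stress-strain loop trace as CSV
    (t_ms, E_<comp>, S_<comp>_kPa)."""
    E, S = loop["E"], loop["S"]
    t = np.arange(len(E), dtype=float) if t_ms is None else np.asarray(t_ms)
    header = f"t_ms,E_{component},S_{component}_kPa"
    np.savetxt(path, np.column_stack([t, E, S]), delimiter=",",
               header=header, comments="", fmt="%.8g")


def contact_pressure(G_contact, params: ContactParams | None = None):
    """Penalty boundary load against wall-cannula contact.

    Zero below the gap-reciprocal threshold G_limit, then linear:
    k_contact (G - G_limit); continuous at the threshold.
    """
    params = params or ContactParams()
    G = np.asarray(G_contact, float)
    if np.any(G < 0):
        raise ValueError("gap reciprocal must be nonnegative")
    out = np.where(G >= params.G_limit,
                   params.k_contact * (G - params.G_limit), 0.0)
    if out.ndim == 0:
        return float(out)
    return out
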