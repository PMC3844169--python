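"""Parameter registry for the pediatric single-ventricle circulation model.

All hemodynamic constants (chamber elastances, valve constants, vascular
resistance/compliance/inertance values) describe a child of roughly 17 kg
with a univentricular heart, a patent atrial septal defect, and a
bidirectional Glenn anastomosis.  Units are fixed throughout the package:
pressure in mmHg, volume in mL, time in s, flow in mL/s, so that
resistance is mmHg·s/mL, compliance mL/mmHg, inertance mmHg·s²/mL and
Bernoulli resistance mmHg·s²/mL².
"""

from __future__ import annotations

import math
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "ParameterSet",
    "default_parameters",
    "scale_parameter",
    "sweep_grid",
    "SWEEP_TARGETS",
    "load_config",
    "save_config",
    "MMHG_PER_DYN_CM2",
    "BLOOD_DENSITY",
]

#: dyn/cm² per mmHg, used to convert CGS Bernoulli/inertance constants.
MMHG_PER_DYN_CM2 = 1.0 / 1333.22

#: Blood density [g/cm³].
BLOOD_DENSITY = 1.06


class ParameterSet(BaseModel):
    """Complete named registry of model constants.

    Every field is addressable by its conventional symbol through
    :meth:`get`; unknown names raise ``KeyError``.  The registry is
    immutable — scaled variants are produced with :func:`scale_parameter`
    or ``model_copy(update=...)``.
    """

    model_config = ConfigDict(frozen=True)

    # --- heart: maximum active (systolic) and baseline (diastolic)
    # elastance of right atrium, left atrium, left ventricle [mmHg/mL]
    E_ras: float = 0.26
    E_rad: float = 0.36
    E_las: float = 0.5
    E_lad: float = 0.7
    E_lvs: float = 6.64
    E_lvd: float = 0.18

    # --- timing [s]
    T_0: float = 0.67
    T_vcp: float = 0.246
    T_vrp: float = 0.147

    # --- chamber viscoelasticity: S_cc = k_S · P_cc, so k_S has units
    # s/mL and S_cc the tabulated mmHg·s/mL
    k_S_ra: float = 5e-4
    k_S_la: float = 5e-4
    k_S_lv: float = 5e-4

    # --- cardiac valves
    L_mv: float = 1.4e-3
    B_mv: float = 8e-5
    R_mv: float = 8e-3
    L_av: float = 1.4e-3
    B_av: float = 1.2e-4
    R_av: float = 1.2e-2

    # --- pulmonary circulation
    C_pt: float = 0.144
    L_pt_l: float = 4e-3
    R_pt_l: float = 1e-3
    L_pt_r: float = 4e-3
    R_pt_r: float = 1e-3
    L_pua_l: float = 6.7e-3
    R_pua_l: float = 0.235
    C_pua_l: float = 0.217
    L_puc_l: float = 4e-3
    R_puc_l: float = 0.173
    C_puc_l: float = 2.35
    L_puv_l: float = 6.7e-3
    R_puv_l: float = 0.103
    C_puv_l: float = 0.97
    L_pua_r: float = 6.7e-3
    R_pua_r: float = 0.235
    C_pua_r: float = 0.217
    L_puc_r: float = 4e-3
    R_puc_r: float = 0.173
    C_puc_r: float = 2.35
    L_puv_r: float = 6.7e-3
    R_puv_r: float = 0.103
    C_puv_r: float = 0.97

    # --- atrial septal defect (bidirectional, no valve)
    L_ASD: float = 5e-4
    R_ASD: float = 1e-3

    # --- aorta
    L_ao_l: float = 3e-2
    R_ao_l: float = 6.5e-2
    L_ao_u: float = 1.5e-2
    R_ao_u: float = 0.15
    C_ao: float = 0.267

    # --- venae cavae
    L_ivc: float = 7.5e-3
    R_ivc: float = 2e-2
    C_ivc: float = 3.95
    L_svc: float = 3.8e-3
    R_svc: float = 6.4e-2
    C_svc: float = 0.54

    # --- systemic circulation (upper = head/arms, lower = splanchnic/legs)
    L_art_l: float = 1.5e-2
    R_art_l: float = 4.22
    C_art_l: float = 0.13
    L_cap_l: float = 4.5e-3
    R_cap_l: float = 0.32
    C_cap_l: float = 6e-2
    L_ven_l: float = 9e-3
    R_ven_l: float = 6.5e-2
    C_ven_l: float = 22.0
    L_art_u: float = 7.5e-3
    R_art_u: float = 2.91
    C_art_u: float = 1.8e-2
    L_cap_u: float = 2.3e-3
    R_cap_u: float = 0.75
    C_cap_u: float = 8.5e-3
    L_ven_u: float = 4.5e-3
    R_ven_u: float = 0.15
    C_ven_u: float = 3.0

    # --- global simulation conditions
    P_it: float = -3.5   # intrathoracic pressure [mmHg]
    P_pc: float = 3.0    # pericardial pressure [mmHg]
    rho: float = BLOOD_DENSITY  # blood density [g/cm³]
    weight: float = 17.0  # body weight [kg]

    # --- mitral regurgitation: effective orifice area [cm²]; 0 = competent
    mv_areg_cm2: float = 0.0

    # Total stressed blood volume [mL].  Not a measured constant: it sets
    # the closed-loop operating point and is calibrated so that the
    # converged Glenn-circulation mean arterial pressure matches its
    # reference value (see simulator.calibrate_total_volume).
    V_tot: float = 370.9

    @model_validator(mode="after")
    def _check_invariants(self) -> "ParameterSet":
        for name, value in self.model_dump().items():
            if name in ("P_it", "P_pc", "mv_areg_cm2"):
                continue
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.mv_areg_cm2 < 0:
            raise ValueError("mv_areg_cm2 must be non-negative")
        if not 0.0 < self.T_vcp + self.T_vrp < self.T_0:
            raise ValueError("timings must satisfy 0 < T_vcp + T_vrp < T_0")
        return self

    def get(self, name: str) -> float:
        """Look up a constant by symbol; unknown names are an error."""
        if name not in type(self).model_fields:
            raise KeyError(f"unknown parameter {name!r}")
        return getattr(self, name)

    @property
    def scaling_metadata(self) -> dict[str, float]:
        """Body-size reference totals for validation reporting.

        Total systemic compliance scales as 2.1·weight and total pulmonary
        compliance as 0.408·weight (mL/mmHg); the per-compartment
        constants above are the model values, these totals are only
        recorded for consistency checks against the scaling laws.
        """
        return {
            "C_sys": 2.1 * self.weight,
            "C_pul": 0.408 * self.weight,
        }


#: Names accepted by scale_parameter and the sweep CLI.  "R_pul" scales
#: every pulmonary resistive element (trunk branches, arterial, capillary
#: and venous segments of both lungs) by a common factor; the others scale
#: a single constant.  E_slv/E_dlv are accepted aliases for the
#: ventricular elastances.
SWEEP_TARGETS = ("R_pul", "R_art_l", "E_lvs", "E_lvd")

_ALIASES = {"E_slv": "E_lvs", "E_dlv": "E_lvd"}

_R_PUL_FIELDS = (
    "R_pt_l", "R_pt_r",
    "R_pua_l", "R_pua_r",
    "R_puc_l", "R_puc_r",
    "R_puv_l", "R_puv_r",
)


def default_parameters(weight: float = 17.0) -> ParameterSet:
    """Return the default parameter registry for a child of given weight.

    The registry constants correspond to a 17 kg patient; ``weight`` is
    stored and used only for the compliance scaling-law metadata
    (``C_sys = 2.1·weight``, ``C_pul = 0.408·weight``) — individual
    compartment values are not rescaled.
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    return ParameterSet(weight=weight)


def scale_parameter(params: ParameterSet, target: str, factor: float) -> ParameterSet:
    """Return a copy of ``params`` with one sweep parameter scaled.

    ``target`` is one of ``R_pul`` (common multiplier on all pulmonary
    resistances), ``R_art_l`` (lower-body arteriolar resistance), ``E_lvs``
    (ventricular systolic elastance) or ``E_lvd`` (ventricular diastolic
    stiffness); ``factor`` must lie in [0.5, 2.5], the 50–250% sweep range.
    All other constants are untouched.
    """
    target = _ALIASES.get(target, target)
    if target not in SWEEP_TARGETS:
        raise KeyError(f"unknown sweep target {target!r}; expected one of {SWEEP_TARGETS}")
    if not 0.5 <= factor <= 2.5:
        raise ValueError(f"factor must lie in [0.5, 2.5], got {factor}")
    if target == "R_pul":
        update = {f: params.get(f) * factor for f in _R_PUL_FIELDS}
    else:
        update = {target: params.get(target) * factor}
    return params.model_copy(update=update)


def sweep_grid(start: float = 0.5, stop: float = 2.5, step: float = 0.1) -> list[float]:
    """Arithmetic grid of scale factors, inclusive of both endpoints."""
    n = int(round((stop - start) / step)) + 1
    grid = [start + i * step for i in range(n)]
    if not math.isclose(grid[-1], stop, rel_tol=0, abs_tol=1e-9):
        raise ValueError("step does not divide the sweep interval")
    return [round(f, 12) for f in grid]


# --------------------------------------------------------------------------
# Config file round-trip.  The on-disk format mirrors the registry symbols
# exactly, with global conditions grouped under `conditions` and an
# optional `sweep` block (target/min/max/step) consumed by the CLI.

_CONDITION_KEYS = ("T_0", "P_it", "P_pc")


def save_config(params: ParameterSet, path: str, sweep: dict[str, Any] | None = None) -> None:
    """Write a YAML config mirroring the parameter registry."""
    data = params.model_dump()
    conditions = {k: data.pop(k) for k in _CONDITION_KEYS}
    doc: dict[str, Any] = {"parameters": data, "conditions": conditions}
    if sweep is not None:
        doc["sweep"] = dict(sweep)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path: str) -> tuple[ParameterSet, dict[str, Any] | None]:
    """Read a YAML config written by :func:`save_config`.

    Returns the parameter set and the optional sweep block (or None).
    Unknown parameter names are rejected.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    fields = dict(doc.get("parameters", {}))
    fields.update(doc.get("conditions", {}))
    known = set(ParameterSet.model_fields)
    unknown = set(fields) - known
    if unknown:
        raise KeyError(f"unknown parameter name(s) in config: {sorted(unknown)}")
    return ParameterSet(**fields), doc.get("sweep")
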