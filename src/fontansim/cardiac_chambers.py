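"""Time-varying elastance model of the three cardiac chambers.

The single-ventricle heart has a right atrium, a left atrium and one
functional (left) ventricle.  Each chamber obeys

    P(t) = E(t) · (V − V0) + S · dV/dt ,        E(t) = E_s · e(t) + E_d

with V0 = 0, a normalized activation e(t) ∈ [0, 1], and a wall
viscoelasticity coefficient proportional to instantaneous chamber
pressure, S = k_S · P.  Substituting S and solving for P gives the closed
form used throughout:

    P = E(t) · V / (1 − k_S · dV/dt)  +  P_pc + P_it ,

where pericardial and intrathoracic pressures act externally on all three
chambers.  The denominator is clamped at 0.5 as a numerical guard; at the
tabulated k_S ≈ 5e-4 s/mL and physiological filling/ejection rates the
correction stays within ~10% and the guard never engages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ChamberParams",
    "ventricular_activation",
    "atrial_activation",
    "chamber_pressure",
    "ATRIAL_PHASE_FRACTION",
]

#: Duration of each atrial activation phase (contraction, relaxation) as a
#: fraction of the cardiac cycle.  The atrial beat is timed so relaxation
#: completes exactly at ventricular contraction onset (atrial kick in late
#: diastole); the atria are fully relaxed throughout ventricular systole.
ATRIAL_PHASE_FRACTION = 0.09


@dataclass(frozen=True)
class ChamberParams:
    """Elastance law constants for one chamber.

    E_s is the peak active elastance (systolic function), E_d the baseline
    stiffness (diastolic function), both mmHg/mL; k_S the viscoelastic
    proportionality constant [s/mL]; the unstressed volume is zero.
    """

    name: str
    E_s: float
    E_d: float
    k_S: float
    is_atrium: bool

    def __post_init__(self) -> None:
        if self.E_s < 0 or self.E_d <= 0:
            raise ValueError(f"{self.name}: require E_s >= 0 and E_d > 0")


def ventricular_activation(t: float, t_vcp: float, t_vrp: float, t_0: float) -> float:
    """Normalized ventricular active-elastance waveform e(t) ∈ [0, 1].

    A raised cosine climbs 0→1 over the contraction period [0, T_vcp],
    a second raised cosine decays 1→0 over the relaxation period
    (T_vcp, T_vcp+T_vrp], and e = 0 for the rest of the cycle.  ``t`` is
    reduced modulo the cycle duration ``t_0``.
    """
    if t_vcp + t_vrp > t_0:
        raise ValueError("activation phases exceed the cardiac cycle")
    t = math.fmod(t, t_0)
    if t < 0:
        t += t_0
    if t <= t_vcp:
        return 0.5 * (1.0 - math.cos(math.pi * t / t_vcp))
    if t <= t_vcp + t_vrp:
        return 0.5 * (1.0 + math.cos(math.pi * (t - t_vcp) / t_vrp))
    return 0.0


def atrial_activation(t: float, t_0: float, phase_fraction: float = ATRIAL_PHASE_FRACTION) -> float:
    """Normalized atrial activation, peaking in late ventricular diastole.

    Same two-cosine shape as the ventricle with contraction and relaxation
    each lasting ``phase_fraction``·T_0; onset is placed so the falling
    limb ends at t = 0 (mod T_0), the instant ventricular contraction
    begins.
    """
    t_phase = phase_fraction * t_0
    onset = t_0 - 2.0 * t_phase
    tau = math.fmod(t - onset, t_0)
    if tau < 0:
        tau += t_0
    return ventricular_activation(tau, t_phase, t_phase, t_0)


def chamber_pressure(
    v: float,
    dv_dt: float,
    e: float,
    params: ChamberParams,
    p_pc: float = 0.0,
    p_it: float = 0.0,
) -> float:
    """Absolute luminal chamber pressure [mmHg].

    Solves the implicit elastance law (S proportional to P) in closed
    form and adds the external pericardial + intrathoracic pressures.
    """
    if v <= 0:
        raise ValueError(f"{params.name}: chamber volume must be positive, got {v}")
    elastance = params.E_s * e + params.E_d
    denom = 1.0 - params.k_S * dv_dt
    if denom < 0.5:
        denom = 0.5
    return elastance * v / denom + p_pc + p_it
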