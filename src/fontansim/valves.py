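"""Two-mode cardiac valve model with optional mitral regurgitation.

An open valve relates its pressure drop to flow through viscous,
Bernoulli and inertial terms,

    ΔP = R·Q + B·Q·|Q| + L·dQ/dt ,

and closes when the gradient reverses while flow has decayed to zero,
which prevents retrograde flow entirely for a competent valve.  A mitral
valve with a regurgitant orifice of effective area A_reg instead enters a
regurgitation mode when the ventricular pressure exceeds the atrial one:
retrograde flow is driven through the same law with Bernoulli resistance
and inertance derived from the orifice geometry,

    B_reg = ρ/2 · (1/A_reg − 1/A_la)² ,
    L_reg = 2ρ√π · (1/√A_reg − 1/√A_la) ,

where A_la is the nominal left-atrial cross-section obtained from the
instantaneous atrial volume assuming a spherical chamber.  Both constants
are converted from CGS to mmHg-based units and recomputed every step as
the atrium fills and empties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

from .parameters import BLOOD_DENSITY, MMHG_PER_DYN_CM2

__all__ = [
    "ValveParams",
    "ValveState",
    "valve_flow_rate",
    "regurgitant_parameters",
    "nominal_atrial_area",
    "update_valve_mode",
    "EPS_Q",
]

#: Flow threshold [mL/s] below which a decelerating jet counts as stopped.
EPS_Q = 1e-3

Mode = Literal["open-forward", "closed", "regurgitant"]


@dataclass(frozen=True)
class ValveParams:
    """Forward-flow constants plus the regurgitant orifice area.

    A_reg = 0 models a competent valve (the regurgitant mode is then
    unreachable).  B_reg/L_reg are not stored: they depend on the
    instantaneous atrial volume and are produced by
    :func:`regurgitant_parameters`.
    """

    R_v: float
    B_v: float
    L_v: float
    A_reg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.R_v, self.B_v, self.L_v) <= 0:
            raise ValueError("forward valve constants must be positive")
        if self.A_reg < 0:
            raise ValueError("regurgitant area must be non-negative")


@dataclass(frozen=True)
class ValveState:
    mode: Mode
    Q: float  # forward-positive transvalve flow [mL/s]


def valve_flow_rate(
    dp: float,
    q: float,
    r_v: float,
    b_v: float,
    l_v: float,
    mode: Mode,
) -> float:
    """dQ/dt [mL/s²] through an open or regurgitant valve.

    The caller selects the forward or regurgitant (B, L) constants to
    match ``mode``; a closed valve carries no flow and has zero rate.
    """
    if mode == "closed":
        return 0.0
    return (dp - r_v * q - b_v * q * abs(q)) / l_v


def nominal_atrial_area(v_la: float) -> float:
    """Cross-sectional area [cm²] of a sphere holding ``v_la`` mL."""
    if v_la <= 0:
        raise ValueError(f"atrial volume must be positive, got {v_la}")
    radius = (3.0 * v_la / (4.0 * math.pi)) ** (1.0 / 3.0)
    return math.pi * radius * radius


def regurgitant_parameters(
    a_reg: float, v_la: float, rho: float = BLOOD_DENSITY
) -> tuple[float, float]:
    """Bernoulli resistance and inertance of the regurgitant jet.

    Returns (B_reg [mmHg·s²/mL²], L_reg [mmHg·s²/mL]) for an orifice of
    ``a_reg`` cm² discharging into an atrium of instantaneous volume
    ``v_la`` mL.  Both vanish as the orifice approaches the atrial
    cross-section and grow without bound as it closes.
    """
    if a_reg <= 0:
        raise ValueError(f"regurgitant area must be positive, got {a_reg}")
    a_la = nominal_atrial_area(v_la)
    if a_reg >= a_la:
        raise ValueError(
            f"regurgitant orifice ({a_reg} cm²) must be smaller than the "
            f"atrial cross-section ({a_la:.3f} cm²)"
        )
    b_reg = 0.5 * rho * (1.0 / a_reg - 1.0 / a_la) ** 2 * MMHG_PER_DYN_CM2
    l_reg = (
        2.0
        * rho
        * math.sqrt(math.pi)
        * (1.0 / math.sqrt(a_reg) - 1.0 / math.sqrt(a_la))
        * MMHG_PER_DYN_CM2
    )
    return b_reg, l_reg


def update_valve_mode(
    state: ValveState,
    p_upstream: float,
    p_downstream: float,
    a_reg: float = 0.0,
    eps_q: float = EPS_Q,
) -> ValveState:
    """Advance the discrete valve mode from the current pressures and flow.

    Transitions (ΔP = P_upstream − P_downstream, forward-positive):

    * open-forward → closed when ΔP < 0 and the forward jet has decayed
      (Q ≤ eps_q); flow is projected to exactly zero.
    * closed → open-forward when ΔP > 0.
    * closed → regurgitant when ΔP < 0 and the valve leaks (a_reg > 0).
    * regurgitant → open-forward when ΔP > 0 and the retrograde jet has
      decayed (Q ≥ −eps_q); any residual retrograde flow is projected to
      zero.  The decay test is one-sided because with a finite step the
      decelerating jet crosses zero between step boundaries and would
      otherwise never satisfy a two-sided |Q| ≤ eps_q window.

    A competent valve (a_reg = 0) can never enter the regurgitant mode.
    """
    dp = p_upstream - p_downstream
    mode, q = state.mode, state.Q
    if mode == "open-forward":
        if dp < 0 and q <= eps_q:
            return ValveState("regurgitant" if a_reg > 0 else "closed", 0.0)
    elif mode == "closed":
        if dp > 0:
            return ValveState("open-forward", q)
        if dp < 0 and a_reg > 0:
            return ValveState("regurgitant", q)
    elif mode == "regurgitant":
        if dp > 0 and q >= -eps_q:
            return ValveState("open-forward", max(q, 0.0))
    else:
        raise ValueError(f"unknown valve mode {mode!r}")
    return state


def with_regurgitation(params: ValveParams, a_reg: float) -> ValveParams:
    """Copy of forward constants with a regurgitant orifice attached."""
    return replace(params, A_reg=a_reg)
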