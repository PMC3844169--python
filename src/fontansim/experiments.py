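"""Simulation experiments: baseline comparison, sweeps, waveform features.

The clinical question is what happens acutely when a Glenn (BCPA)
circulation is completed to a Fontan (TCPC): both configurations are run
with one shared parameter set and one shared total stressed volume, and
the change in transpulmonary flow and inferior-vena-cava ("central
venous") pressure is expressed as a percentage of the pre-completion
value.  Sweeps repeat this for pulmonary vascular resistance, lower-body
arteriolar resistance, ventricular systolic and diastolic elastance
(50–250% of default) and for mitral regurgitation severity
(orifice area 0.01–0.21 cm²).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .parameters import ParameterSet, scale_parameter, sweep_grid
from .simulator import DEFAULT_DT, SimulationResult, run_to_steady_state
from .vascular_network import build_topology

__all__ = [
    "HemodynamicSummary",
    "PerioperativeChange",
    "summarize",
    "perioperative_change",
    "parameter_sweep",
    "regurgitation_sweep",
    "waveform_features",
    "WaveformFeatures",
    "run_pair",
]


@dataclass(frozen=True)
class HemodynamicSummary:
    """Cycle-averaged hemodynamics of one converged run.

    Pressures in mmHg, flows in mL/s, volumes in mL, EF in percent;
    mQ_pul is total pulmonary venous return, CO the mean aortic-valve
    flow, and the regurgitation fraction the retrograde-to-forward
    transmitral volume ratio over one cycle.
    """

    config: str
    mP_svc: float
    mP_ivc: float
    mP_pa: float
    mP_la: float
    mP_art: float
    SV: float
    EDV: float
    EF: float
    mQ_pul: float
    CO: float
    regurgitation_fraction: float

    def as_dict(self) -> dict[str, float | str]:
        return asdict(self)


@dataclass(frozen=True)
class PerioperativeChange:
    """Relative change of a quantity across the Glenn→Fontan completion."""

    dQ_pul_pct: float
    dP_ivc_pct: float
    target: str | None = None
    factor: float | None = None
    a_reg: float | None = None


@dataclass(frozen=True)
class WaveformFeatures:
    n_peaks: int
    retrograde: bool
    pulse: float  # max - min over a cycle


def _cycle_mean_la_pressure(result: SimulationResult) -> float:
    """Mean LA pressure reconstructed from the LA volume waveform."""
    # LA pressure is not a state variable; rebuild it from the elastance
    # law exactly as the solver does.
    from .cardiac_chambers import (
        ATRIAL_PHASE_FRACTION,
        ChamberParams,
        atrial_activation,
        chamber_pressure,
    )

    params = result._params
    v = result.series("V_LA")
    q_in = (
        result.series("Q_puv_l")
        + result.series("Q_puv_r")
        + result.series("Q_asd")
        - result.series("Q_mv")
    )
    cp = ChamberParams("LA", params.E_las, params.E_lad, params.k_S_la, True)
    t = result.time
    p = np.array(
        [
            chamber_pressure(vi, qi, atrial_activation(ti, params.T_0), cp, params.P_pc, params.P_it)
            for vi, qi, ti in zip(v, q_in, t)
        ]
    )
    n = result.states.shape[0] // result.n_keep
    return float(p[-n:].mean())


def summarize(result: SimulationResult, params: ParameterSet) -> HemodynamicSummary:
    """Reduce a converged run to the standard cycle-averaged variables."""
    if not result.converged:
        raise ValueError("refusing to summarize a non-converged run")
    result._params = params  # used for LA pressure reconstruction

    n = result.states.shape[0] // result.n_keep  # samples in final cycle
    sl = slice(result.states.shape[0] - n, result.states.shape[0])

    v_lv = result.series("V_LV")[sl]
    edv = float(v_lv.max())
    sv = float(v_lv.max() - v_lv.min())
    ef = 100.0 * sv / edv if edv > 0 else 0.0

    q_mv = result.series("Q_mv")[sl]
    fwd = float(np.clip(q_mv, 0.0, None).sum()) * result.dt
    retro = abs(float(np.clip(q_mv, None, 0.0).sum())) * result.dt
    reg_frac = retro / fwd if fwd > 0 else 0.0

    mean = result.mean
    return HemodynamicSummary(
        config=result.topology.config,
        mP_svc=mean("P_svc"),
        mP_ivc=mean("P_ivc"),
        mP_pa=mean("P_pt"),
        mP_la=_cycle_mean_la_pressure(result),
        mP_art=mean("P_ao"),
        SV=sv,
        EDV=edv,
        EF=ef,
        mQ_pul=mean("Q_puv_l") + mean("Q_puv_r"),
        CO=mean("Q_av"),
        regurgitation_fraction=reg_frac,
    )


def perioperative_change(
    glenn: HemodynamicSummary, tcpc: HemodynamicSummary, **labels
) -> PerioperativeChange:
    """Percentage change of pulmonary flow and IVC pressure, Glenn→Fontan."""
    if glenn.mQ_pul == 0 or glenn.mP_ivc == 0:
        raise ZeroDivisionError("pre-completion reference value is zero")
    return PerioperativeChange(
        dQ_pul_pct=100.0 * (tcpc.mQ_pul - glenn.mQ_pul) / glenn.mQ_pul,
        dP_ivc_pct=100.0 * (tcpc.mP_ivc - glenn.mP_ivc) / glenn.mP_ivc,
        **labels,
    )


def run_pair(
    params: ParameterSet,
    dt: float = DEFAULT_DT,
    tol: float = 1e-6,
    max_cycles: int = 800,
) -> tuple[HemodynamicSummary, HemodynamicSummary]:
    """Run both configurations with one shared parameter set."""
    summaries = []
    for config in ("BCPA", "TCPC"):
        topo = build_topology(config, params)
        res = run_to_steady_state(topo, params, dt=dt, tol=tol, max_cycles=max_cycles)
        summaries.append(summarize(res, params))
    return tuple(summaries)


def parameter_sweep(
    target: Literal["R_pul", "R_art_l", "E_lvs", "E_lvd"],
    params: ParameterSet,
    grid: Sequence[float] | None = None,
    dt: float = DEFAULT_DT,
    tol: float = 1e-6,
    max_cycles: int = 800,
) -> pd.DataFrame:
    """Perioperative changes across a scale-factor grid for one parameter.

    Each row scales ``target`` by one factor (all other constants and the
    calibrated total volume untouched), runs both configurations to
    steady state, and reports the percentage changes plus the absolute
    summaries.  Non-convergence of a row is flagged, not fatal.
    """
    grid = sweep_grid() if grid is None else list(grid)
    rows = []
    for factor in grid:
        p = scale_parameter(params, target, factor)
        row: dict = {"target": target, "factor": factor, "converged": True}
        try:
            glenn, tcpc = run_pair(p, dt=dt, tol=tol, max_cycles=max_cycles)
        except (ValueError, FloatingPointError):
            row["converged"] = False
            rows.append(row)
            continue
        change = perioperative_change(glenn, tcpc)
        row.update(dQ_pul_pct=change.dQ_pul_pct, dP_ivc_pct=change.dP_ivc_pct)
        row.update({f"glenn_{k}": v for k, v in glenn.as_dict().items() if k != "config"})
        row.update({f"tcpc_{k}": v for k, v in tcpc.as_dict().items() if k != "config"})
        rows.append(row)
    return pd.DataFrame(rows)


def regurgitation_sweep(
    params: ParameterSet,
    areas: Sequence[float] | None = None,
    dt: float = DEFAULT_DT,
    tol: float = 1e-6,
    max_cycles: int = 800,
) -> pd.DataFrame:
    """Perioperative changes across mitral regurgitant orifice areas.

    Severity is reported as the Glenn-run regurgitation fraction
    (retrograde/forward transmitral volume), the conventional abscissa
    for these sweeps.  Default grid: 11 evenly spaced areas over
    0.01–0.21 cm².
    """
    if areas is None:
        areas = np.linspace(0.01, 0.21, 11).round(6).tolist()
    rows = []
    for a_reg in areas:
        if a_reg <= 0:
            raise ValueError("regurgitant areas must be positive")
        p = params.model_copy(update={"mv_areg_cm2": float(a_reg)})
        row: dict = {"a_reg_cm2": float(a_reg), "converged": True}
        try:
            glenn, tcpc = run_pair(p, dt=dt, tol=tol, max_cycles=max_cycles)
        except (ValueError, FloatingPointError):
            row["converged"] = False
            rows.append(row)
            continue
        change = perioperative_change(glenn, tcpc)
        row.update(
            regurgitation_fraction=glenn.regurgitation_fraction,
            dQ_pul_pct=change.dQ_pul_pct,
            dP_ivc_pct=change.dP_ivc_pct,
        )
        row.update({f"glenn_{k}": v for k, v in glenn.as_dict().items() if k != "config"})
        row.update({f"tcpc_{k}": v for k, v in tcpc.as_dict().items() if k != "config"})
        rows.append(row)
    return pd.DataFrame(rows)


_VESSEL_FLOW = {"IVC": "Q_ivc", "SVC": "Q_svc", "PA": "Q_pt_l"}


def waveform_features(
    result: SimulationResult,
    vessel: Literal["IVC", "SVC", "PA"],
    prominence_fraction: float = 0.05,
) -> WaveformFeatures:
    """Morphology of a venous/pulmonary flow waveform over one cycle.

    Counts local maxima whose prominence exceeds ``prominence_fraction``
    of the waveform range (two cycles are scanned and the central one
    counted, so peaks at the cycle wrap are not lost), and reports whether
    retrograde flow occurs and the peak-to-peak amplitude.
    """
    q = result.series(_VESSEL_FLOW[vessel])
    n = result.states.shape[0] // result.n_keep
    cycle = q[-n:]
    rng = float(cycle.max() - cycle.min())
    if rng == 0.0:
        return WaveformFeatures(n_peaks=0, retrograde=bool(cycle.min() < 0), pulse=0.0)
    doubled = np.concatenate([cycle, cycle])
    peaks, _ = find_peaks(doubled, prominence=prominence_fraction * rng)
    n_peaks = int(np.sum((peaks >= n // 2) & (peaks < n // 2 + n)))
    return WaveformFeatures(
        n_peaks=n_peaks,
        retrograde=bool(cycle.min() < -1e-9),
        pulse=rng,
    )
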