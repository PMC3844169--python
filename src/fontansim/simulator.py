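"""Closed-loop assembly, RK4 time integration and volume calibration.

The full circulation is an autonomous-in-structure, periodically forced
ODE system: compartment pressures and segment flows from the vascular
network, chamber volumes from the heart, with discrete valve modes
switching at step boundaries.  The system is integrated with a fixed-step
fourth-order Runge-Kutta scheme (default dt = 1e-4 s, 6700 steps per
0.67 s cycle) until the cycle means of every state variable stop changing
between consecutive beats, i.e. until the periodic steady state (limit
cycle) is reached.  Everything is deterministic — two runs with identical
inputs are bit-identical.

Total stressed blood volume V_tot closes the system: it sets the
operating point of the loop and is not directly measurable, so it is
calibrated by bisection so that the converged Glenn-configuration mean
arterial pressure matches a reference value, then frozen for every other
simulation (parameter sweeps and the Fontan-completion run).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import _engine
from .cardiac_chambers import (
    ATRIAL_PHASE_FRACTION,
    ChamberParams,
    atrial_activation,
    chamber_pressure,
    ventricular_activation,
)
from .parameters import MMHG_PER_DYN_CM2, ParameterSet
from .valves import valve_flow_rate, regurgitant_parameters
from .vascular_network import (
    CHAMBERS,
    CircuitTopology,
    compartment_pressure_rate,
    segment_flow_rate,
)

__all__ = [
    "StateLayout",
    "SimulationResult",
    "state_derivative",
    "initial_state",
    "run_to_steady_state",
    "calibrate_total_volume",
    "DEFAULT_DT",
    "MAP_REFERENCE",
]

#: Default integration step [s]; resolves valve transients (6700 steps/cycle).
DEFAULT_DT = 1e-4

#: Reference Glenn mean arterial pressure [mmHg] used as calibration anchor.
MAP_REFERENCE = 72.1


class StateLayout:
    """Index bookkeeping for the packed state vector.

    Layout: compartment pressures (topology order), then segment flows,
    then chamber volumes (RA, LA, LV).
    """

    def __init__(self, topology: CircuitTopology):
        self.comp_names = tuple(c.name for c in topology.compartments)
        self.seg_names = tuple(s.name for s in topology.segments)
        self.n_comp = len(self.comp_names)
        self.n_seg = len(self.seg_names)
        self.n = self.n_comp + self.n_seg + 3
        self._p = {n: i for i, n in enumerate(self.comp_names)}
        self._q = {n: self.n_comp + i for i, n in enumerate(self.seg_names)}
        self._v = {ch: self.n_comp + self.n_seg + i for i, ch in enumerate(CHAMBERS)}

    def p_index(self, compartment: str) -> int:
        return self._p[compartment]

    def q_index(self, segment: str) -> int:
        return self._q[segment]

    def v_index(self, chamber: str) -> int:
        return self._v[chamber]

    # node indices in the engine's combined pressure vector
    def node_index(self, name: str) -> int:
        if name in self._p:
            return self._p[name]
        return self.n_comp + CHAMBERS.index(name)

    @property
    def column_names(self) -> list[str]:
        return (
            [f"P_{n}" for n in self.comp_names]
            + [f"Q_{n}" for n in self.seg_names]
            + [f"V_{ch}" for ch in CHAMBERS]
        )


@dataclass
class SimulationResult:
    """Waveforms over the final retained cycles plus solver metadata."""

    topology: CircuitTopology
    layout: StateLayout
    time: np.ndarray          # absolute time [s], uniform grid
    states: np.ndarray        # (n_samples, n_states)
    cycle_means: np.ndarray   # means over the last cycle
    dt: float
    cycles_run: int
    n_keep: int
    converged: bool
    residual: float
    valve_modes: np.ndarray = field(default_factory=lambda: np.array([0, 0]))
    final_state: np.ndarray | None = None

    @property
    def waveforms(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.layout.column_names)
        df.insert(0, "t_s", self.time)
        return df

    def mean(self, column: str) -> float:
        """Cycle mean of one state variable (e.g. 'P_ivc', 'Q_av')."""
        names = self.layout.column_names
        return float(self.cycle_means[names.index(column)])

    def series(self, column: str) -> np.ndarray:
        return self.states[:, self.layout.column_names.index(column)]

    def total_volume(self) -> np.ndarray:
        """Instantaneous total stressed volume along the retained samples."""
        v = np.zeros(len(self.time))
        for c in self.topology.compartments:
            p = self.series(f"P_{c.name}")
            p_ext = c.external_pressure(self._p_it)
            v += c.C * (p - p_ext)
        for ch in CHAMBERS:
            v += self.series(f"V_{ch}")
        return v

    _p_it: float = -3.5


# --------------------------------------------------------------------------
# packing


def _chamber_params(params: ParameterSet) -> tuple[ChamberParams, ...]:
    return (
        ChamberParams("RA", params.E_ras, params.E_rad, params.k_S_ra, True),
        ChamberParams("LA", params.E_las, params.E_lad, params.k_S_la, True),
        ChamberParams("LV", params.E_lvs, params.E_lvd, params.k_S_lv, False),
    )


@dataclass
class _Packed:
    layout: StateLayout
    seg_up: np.ndarray
    seg_dn: np.ndarray
    seg_r: np.ndarray
    seg_l: np.ndarray
    seg_b: np.ndarray
    seg_kind: np.ndarray
    comp_c: np.ndarray
    comp_pext: np.ndarray
    ch_es: np.ndarray
    ch_ed: np.ndarray
    ch_ks: np.ndarray
    ch_pext: float
    mv_si: int
    av_si: int


def _pack(topology: CircuitTopology, params: ParameterSet) -> _Packed:
    layout = StateLayout(topology)
    segs = topology.segments
    kind_code = {"vessel": _engine.VESSEL, "mitral": _engine.MITRAL, "aortic": _engine.AORTIC}
    chambers = _chamber_params(params)
    return _Packed(
        layout=layout,
        seg_up=np.array([layout.node_index(s.upstream) for s in segs], dtype=np.int64),
        seg_dn=np.array([layout.node_index(s.downstream) for s in segs], dtype=np.int64),
        seg_r=np.array([s.R for s in segs]),
        seg_l=np.array([s.L for s in segs]),
        seg_b=np.array([s.B for s in segs]),
        seg_kind=np.array([kind_code[s.kind] for s in segs], dtype=np.int64),
        comp_c=np.array([c.C for c in topology.compartments]),
        comp_pext=np.array(
            [c.external_pressure(params.P_it) for c in topology.compartments]
        ),
        ch_es=np.array([c.E_s for c in chambers]),
        ch_ed=np.array([c.E_d for c in chambers]),
        ch_ks=np.array([c.k_S for c in chambers]),
        ch_pext=params.P_pc + params.P_it,
        mv_si=[s.kind for s in segs].index("mitral"),
        av_si=[s.kind for s in segs].index("aortic"),
    )


# --------------------------------------------------------------------------
# reference right-hand side (pure Python, built from the module equations)


def state_derivative(
    x: np.ndarray,
    t: float,
    topology: CircuitTopology,
    params: ParameterSet,
    mv_mode: int = _engine.OPEN,
    av_mode: int = _engine.OPEN,
) -> np.ndarray:
    """Time derivative of the packed state vector.

    Slow, object-model reference implementation composed from the
    per-element equation functions of the network, chamber and valve
    modules; the compiled kernel must agree with it exactly.  Valve modes
    use the engine encoding (1 open, 0 closed, -1 regurgitant).
    """
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state")
    layout = StateLayout(topology)
    dx = np.zeros_like(x)

    # net inflow per node
    net: dict[str, float] = {n: 0.0 for n in layout.comp_names + CHAMBERS}
    for s in topology.segments:
        q = x[layout.q_index(s.name)]
        net[s.upstream] -= q
        net[s.downstream] += q

    # chamber pressures from the elastance law
    chambers = _chamber_params(params)
    pressures: dict[str, float] = {
        n: x[layout.p_index(n)] for n in layout.comp_names
    }
    for cp in chambers:
        v = x[layout.v_index(cp.name)]
        if cp.is_atrium:
            e = atrial_activation(t, params.T_0, ATRIAL_PHASE_FRACTION)
        else:
            e = ventricular_activation(t, params.T_vcp, params.T_vrp, params.T_0)
        pressures[cp.name] = chamber_pressure(
            v, net[cp.name], e, cp, params.P_pc, params.P_it
        )

    for c in topology.compartments:
        dx[layout.p_index(c.name)] = compartment_pressure_rate(net[c.name], 0.0, c.C)

    for s in topology.segments:
        qi = layout.q_index(s.name)
        q = x[qi]
        dp = pressures[s.upstream] - pressures[s.downstream]
        if s.kind == "mitral":
            if mv_mode == _engine.CLOSED:
                dx[qi] = 0.0
            elif mv_mode == _engine.REGURGITANT:
                b_reg, l_reg = regurgitant_parameters(
                    params.mv_areg_cm2, x[layout.v_index("LA")], params.rho
                )
                dx[qi] = valve_flow_rate(dp, q, s.R, b_reg, l_reg, "regurgitant")
            else:
                dx[qi] = valve_flow_rate(dp, q, s.R, s.B, s.L, "open-forward")
        elif s.kind == "aortic":
            if av_mode == _engine.CLOSED:
                dx[qi] = 0.0
            else:
                dx[qi] = valve_flow_rate(dp, q, s.R, s.B, s.L, "open-forward")
        else:
            dx[qi] = segment_flow_rate(
                pressures[s.upstream], pressures[s.downstream], q, s.R, s.L
            )

    for ch in CHAMBERS:
        dx[layout.v_index(ch)] = net[ch]
    return dx


# --------------------------------------------------------------------------
# integration


#: Initial chamber volume guesses [mL]: atria mid-filling, ventricle near
#: its end-diastolic volume.  Only the converged limit cycle matters; the
#: convergence criterion guards against dependence on these.
_V_INIT = {"RA": 8.0, "LA": 8.0, "LV": 30.0}


def initial_state(topology: CircuitTopology, params: ParameterSet) -> np.ndarray:
    """Distribute V_tot at a uniform transmural pressure; zero flows.

    The remaining volume after the chamber guesses is shared among the
    compliant compartments proportionally to compliance, i.e. all start
    at the same transmural pressure, so the initial total stressed volume
    equals V_tot exactly.
    """
    layout = StateLayout(topology)
    x = np.zeros(layout.n)
    v_chambers = sum(_V_INIT.values())
    c_total = sum(c.C for c in topology.compartments)
    v_vascular = params.V_tot - v_chambers
    if v_vascular <= 0:
        raise ValueError(f"V_tot = {params.V_tot} mL cannot fill the chambers")
    p_tm = v_vascular / c_total
    for c in topology.compartments:
        x[layout.p_index(c.name)] = p_tm + c.external_pressure(params.P_it)
    for ch, v in _V_INIT.items():
        x[layout.v_index(ch)] = v
    return x


def run_to_steady_state(
    topology: CircuitTopology,
    params: ParameterSet,
    dt: float = DEFAULT_DT,
    tol: float = 1e-4,
    max_cycles: int = 400,
    n_keep: int = 2,
    min_cycles: int = 5,
) -> SimulationResult:
    """Integrate to the periodic steady state and return the final cycles.

    Convergence: cycle means of every state variable are averaged over
    6-beat blocks and the maximum relative change between the last two
    blocks must fall below ``tol`` (denominators floored at 1 to keep
    near-zero flows from stalling the criterion).  Block averaging is
    needed because valve switching is quantized to the time step, which
    can leave a tiny (relative ~1e-4) period-2 or period-3 orbit in the
    cycle means that consecutive-beat comparison would never resolve;
    averaging cancels it while genuine drift is still detected.
    Divergence (non-finite state) raises; non-convergence within
    ``max_cycles`` is flagged in the result metadata, not fatal.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n_steps = int(round(params.T_0 / dt))
    if abs(n_steps * dt - params.T_0) > 1e-9 * params.T_0:
        raise ValueError("dt must divide the cardiac cycle T_0")
    pk = _pack(topology, params)
    x = initial_state(topology, params)
    modes = np.array([_engine.CLOSED, _engine.CLOSED], dtype=np.int64)

    breg_coef = 0.5 * params.rho * MMHG_PER_DYN_CM2
    lreg_coef = 2.0 * params.rho * math.sqrt(math.pi) * MMHG_PER_DYN_CM2
    ta_phase = ATRIAL_PHASE_FRACTION * params.T_0
    empty = np.zeros((0, pk.layout.n))

    def cycle(cyc_idx: int, rec: np.ndarray, do_rec: bool) -> np.ndarray:
        return _engine.run_cycle(
            x, cyc_idx * params.T_0, n_steps, dt,
            pk.layout.n_comp, pk.layout.n_seg,
            pk.seg_up, pk.seg_dn, pk.seg_r, pk.seg_l, pk.seg_b, pk.seg_kind,
            pk.comp_c, pk.comp_pext,
            pk.ch_es, pk.ch_ed, pk.ch_ks, pk.ch_pext,
            params.T_0, params.T_vcp, params.T_vrp, ta_phase,
            params.mv_areg_cm2, breg_coef, lreg_coef,
            1e-3,
            pk.mv_si, pk.av_si,
            pk.layout.node_index("LA"), pk.layout.node_index("LV"),
            pk.layout.node_index("ao"),
            modes,
            rec, do_rec,
        )

    block = 6
    history: list[np.ndarray] = []
    residual = math.inf
    converged = False
    cycles_run = 0
    for k in range(max_cycles):
        means = cycle(k, empty, False)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"solution diverged in cycle {k}")
        cycles_run = k + 1
        history.append(means)
        if len(history) >= 2 * block:
            curr = np.mean(history[-block:], axis=0)
            prev = np.mean(history[-2 * block : -block], axis=0)
            denom = np.maximum(np.abs(prev), 1.0)
            residual = float(np.max(np.abs(curr - prev) / denom))
            if residual < tol and cycles_run >= min_cycles:
                converged = True
                break

    # retained, recorded cycles
    record = np.empty((n_keep * n_steps, pk.layout.n))
    last_means = None
    for j in range(n_keep):
        last_means = cycle(cycles_run + j, record[j * n_steps : (j + 1) * n_steps], True)
    cycles_run += n_keep
    time = (cycles_run - n_keep) * params.T_0 + dt * np.arange(n_keep * n_steps)

    result = SimulationResult(
        topology=topology,
        layout=pk.layout,
        time=time,
        states=record,
        cycle_means=np.asarray(last_means),
        dt=dt,
        cycles_run=cycles_run,
        n_keep=n_keep,
        converged=converged,
        residual=residual,
        valve_modes=modes.copy(),
        final_state=x.copy(),
    )
    result._p_it = params.P_it
    return result


def calibrate_total_volume(
    topology_bcpa: CircuitTopology,
    params: ParameterSet,
    target: float = MAP_REFERENCE,
    bracket: tuple[float, float] = (200.0, 1200.0),
    tol_mmhg: float = 0.1,
    dt: float = DEFAULT_DT,
    ss_tol: float = 1e-6,
    max_cycles: int = 800,
) -> float:
    """Bisect V_tot so the converged Glenn mean arterial pressure hits target.

    Mean arterial pressure is monotonically increasing in total stressed
    volume, so plain bisection is robust.  The bracket is expanded
    downward/upward (within physical limits) if it does not straddle the
    target.  Returns the calibrated V_tot [mL]; callers freeze it for all
    subsequent runs.
    """
    if topology_bcpa.config != "BCPA":
        raise ValueError("calibration is defined on the Glenn (BCPA) configuration")

    def map_at(v_tot: float) -> float:
        p = params.model_copy(update={"V_tot": v_tot})
        res = run_to_steady_state(
            topology_bcpa, p, dt=dt, tol=ss_tol, max_cycles=max_cycles
        )
        return res.mean("P_ao")

    lo, hi = bracket
    f_lo = map_at(lo) - target
    f_hi = map_at(hi) - target
    expand = 0
    while f_lo > 0 and lo > 60.0:
        lo = max(lo * 0.5, 60.0)
        f_lo = map_at(lo) - target
        expand += 1
        if expand > 6:
            break
    while f_hi < 0 and hi < 5000.0:
        hi = min(hi * 1.5, 5000.0)
        f_hi = map_at(hi) - target
        expand += 1
        if expand > 12:
            break
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"bracket [{lo}, {hi}] mL does not straddle the target pressure {target} mmHg"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = map_at(mid) - target
        if abs(f_mid) < tol_mmhg:
            return mid
        if f_mid > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
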