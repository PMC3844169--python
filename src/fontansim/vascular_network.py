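"""Compartments, flow segments and the two cavopulmonary circuit wirings.

The circulation is a closed directed circuit of compliant pressure nodes
(compartments and cardiac chambers) connected by resistive–inertial flow
segments.  Mass conservation at a compliant node gives

    dP/dt = (Q_in − Q_out) / C

and momentum conservation along a segment gives

    dQ/dt = (P_up − Q·R − P_down) / L .

Two topologies are provided.  In the Glenn (BCPA) circuit the superior
vena cava drains into the pulmonary trunk while inferior vena cava blood
returns to the right atrium and crosses the atrial septal defect into the
left heart.  The Fontan completion (TCPC) re-terminates the IVC segment
at the pulmonary trunk; nothing else changes — the right atrium stays in
the circuit as a blind pouch communicating with the left atrium through
the ASD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

from .parameters import ParameterSet

__all__ = [
    "Compartment",
    "FlowSegment",
    "CircuitTopology",
    "compartment_pressure_rate",
    "segment_flow_rate",
    "build_topology",
    "CHAMBERS",
]

#: Cardiac chamber node names, in canonical order.
CHAMBERS = ("RA", "LA", "LV")


def compartment_pressure_rate(q_in_total: float, q_out_total: float, c: float) -> float:
    """Rate of change of compartment pressure [mmHg/s] from net inflow."""
    if c <= 0:
        raise ValueError(f"compliance must be positive, got {c}")
    return (q_in_total - q_out_total) / c


def segment_flow_rate(p_up: float, p_down: float, q: float, r: float, l: float) -> float:
    """Rate of change of segment flow [mL/s²] from the pressure gradient."""
    if l <= 0:
        raise ValueError(f"inertance must be positive, got {l}")
    return (p_up - q * r - p_down) / l


@dataclass(frozen=True)
class Compartment:
    """A compliant vascular pressure node.

    ``external_pressure_ref`` selects the pressure outside the vessel
    wall: thoracic compartments feel the intrathoracic pressure, the
    extrathoracic systemic beds feel ambient (0 mmHg).  Stored pressure is
    absolute luminal pressure; contained stressed volume is
    C·(P − P_ext).
    """

    name: str
    C: float
    external_pressure_ref: Literal["intrathoracic", "ambient"] = "ambient"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"compartment {self.name}: compliance must be positive")

    def external_pressure(self, p_it: float) -> float:
        return p_it if self.external_pressure_ref == "intrathoracic" else 0.0


@dataclass(frozen=True)
class FlowSegment:
    """A resistive–inertial connection between two pressure nodes.

    ``kind`` distinguishes plain vessels (retrograde flow permitted) from
    the two cardiac valves, which carry a Bernoulli resistance and
    open/close logic handled by the valves module.
    """

    name: str
    upstream: str
    downstream: str
    R: float
    L: float
    B: float = 0.0
    kind: Literal["vessel", "mitral", "aortic"] = "vessel"

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError(f"segment {self.name}: resistance must be non-negative")
        if self.L <= 0:
            raise ValueError(f"segment {self.name}: inertance must be positive")


@dataclass(frozen=True)
class CircuitTopology:
    """Full wiring of one surgical configuration."""

    config: Literal["BCPA", "TCPC"]
    compartments: tuple[Compartment, ...]
    segments: tuple[FlowSegment, ...]
    chambers: tuple[str, ...] = field(default=CHAMBERS)

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.compartments) + self.chambers

    def compartment(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(f"unknown compartment {name!r}")

    def segment(self, name: str) -> FlowSegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"unknown segment {name!r}")

    def inflows(self, node: str) -> tuple[FlowSegment, ...]:
        return tuple(s for s in self.segments if s.downstream == node)

    def outflows(self, node: str) -> tuple[FlowSegment, ...]:
        return tuple(s for s in self.segments if s.upstream == node)

    def to_json(self) -> str:
        """Adjacency description (nodes, edges, element constants)."""
        doc = {
            "config": self.config,
            "nodes": [
                {
                    "name": c.name,
                    "C": c.C,
                    "external_pressure_ref": c.external_pressure_ref,
                }
                for c in self.compartments
            ]
            + [{"name": ch, "kind": "chamber"} for ch in self.chambers],
            "edges": [
                {
                    "name": s.name,
                    "from": s.upstream,
                    "to": s.downstream,
                    "R": s.R,
                    "L": s.L,
                    "B": s.B,
                    "kind": s.kind,
                }
                for s in self.segments
            ],
        }
        return json.dumps(doc, indent=2)


# thoracic cage contents: great veins, aorta, lungs (heart handled separately)
_THORACIC = frozenset(
    {
        "pt",
        "pua_l", "puc_l", "puv_l",
        "pua_r", "puc_r", "puv_r",
        "ao",
        "svc", "ivc",
    }
)


def _compartment(name: str, p: ParameterSet) -> Compartment:
    ref = "intrathoracic" if name in _THORACIC else "ambient"
    return Compartment(name=name, C=p.get(f"C_{name}"), external_pressure_ref=ref)


def build_topology(config: Literal["BCPA", "TCPC"], params: ParameterSet) -> CircuitTopology:
    """Assemble the circuit for one surgical configuration.

    The two wirings differ in exactly one edge: the IVC outlet terminates
    at the right atrium (BCPA) or at the pulmonary trunk node (TCPC).
    """
    if config not in ("BCPA", "TCPC"):
        raise ValueError(f"unknown configuration tag {config!r}")
    p = params

    names = [
        "ao",
        "art_u", "cap_u", "ven_u", "svc",
        "art_l", "cap_l", "ven_l", "ivc",
        "pt",
        "pua_l", "puc_l", "puv_l",
        "pua_r", "puc_r", "puv_r",
    ]
    compartments = tuple(_compartment(n, p) for n in names)

    ivc_outlet = "RA" if config == "BCPA" else "pt"

    def seg(name: str, up: str, down: str, sym: str | None = None) -> FlowSegment:
        sym = sym or name
        return FlowSegment(name, up, down, R=p.get(f"R_{sym}"), L=p.get(f"L_{sym}"))

    segments = (
        # systemic arterial tree
        seg("ao_u", "ao", "art_u"),
        seg("ao_l", "ao", "art_l"),
        # upper body: arterioles -> capillaries -> veins -> SVC -> pulmonary trunk
        seg("art_u", "art_u", "cap_u"),
        seg("cap_u", "cap_u", "ven_u"),
        seg("ven_u", "ven_u", "svc"),
        seg("svc", "svc", "pt"),
        # lower body: arterioles -> capillaries -> veins -> IVC -> RA or trunk
        seg("art_l", "art_l", "cap_l"),
        seg("cap_l", "cap_l", "ven_l"),
        seg("ven_l", "ven_l", "ivc"),
        seg("ivc", "ivc", ivc_outlet),
        # atrial septal defect: bidirectional RA <-> LA pathway, no valve
        seg("asd", "RA", "LA", sym="ASD"),
        # pulmonary circulation, left and right lungs in parallel
        seg("pt_l", "pt", "pua_l"),
        seg("pua_l", "pua_l", "puc_l"),
        seg("puc_l", "puc_l", "puv_l"),
        seg("puv_l", "puv_l", "LA"),
        seg("pt_r", "pt", "pua_r"),
        seg("pua_r", "pua_r", "puc_r"),
        seg("puc_r", "puc_r", "puv_r"),
        seg("puv_r", "puv_r", "LA"),
        # cardiac valves
        FlowSegment("mv", "LA", "LV", R=p.R_mv, L=p.L_mv, B=p.B_mv, kind="mitral"),
        FlowSegment("av", "LV", "ao", R=p.R_av, L=p.L_av, B=p.B_av, kind="aortic"),
    )
    return CircuitTopology(config=config, compartments=compartments, segments=segments)
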