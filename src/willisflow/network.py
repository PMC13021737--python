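"""Domain types and resistance/permeability physics for the lumped CoW network.

The Circle of Willis (CoW) is represented as a directed graph of resistive
vessel segments between pressure nodes, with three prescribed-flow inlets
(LICA, RICA, BA), eight Windkessel outlets (bilateral ACA/MCA/PCA/SCA),
the communicating arteries of a complete CoW, an optional lumped
leptomeningeal-collateral element per hemisphere (distal ACA -> distal MCA),
and an optional porous-clot element occluding the proximal M1 segment of
the left MCA.

Segment resistances follow Hagen-Poiseuille; the clot element is a lumped
Darcy resistance whose permeability comes from the Davies correlation for
fibrous media (here, a fibrin clot).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import networkx as nx
import yaml

__all__ = [
    "FluidProperties",
    "VesselSegment",
    "CollateralScore",
    "CollateralModel",
    "ClotModel",
    "CoWNetwork",
    "hagen_poiseuille_resistance",
    "davies_permeability",
    "clot_darcy_resistance",
    "build_network",
    "load_network_config",
    "default_network_config",
    "NetworkConfigError",
]

INLET_NAMES = ("LICA", "RICA", "BA")
OUTLET_NAMES = ("LACA", "LMCA", "LPCA", "LSCA", "RACA", "RMCA", "RPCA", "RSCA")


class NetworkConfigError(ValueError):
    """Raised for invalid or inconsistent network descriptions."""


# ---------------------------------------------------------------------------
# elementary physics
# ---------------------------------------------------------------------------

def hagen_poiseuille_resistance(length: float, diameter: float,
                                dynamic_viscosity: float) -> float:
    """Poiseuille resistance 128*mu*L/(pi*D^4) of a cylindrical segment.

    Parameters are in SI (m, m, Pa.s); the result is in Pa.s/m^3 and scales
    as 1/D^4, which is what makes collateral calibre the dominant control on
    collateral resistance.
    """
    if length <= 0 or diameter <= 0 or dynamic_viscosity <= 0:
        raise ValueError("length, diameter and viscosity must be positive")
    return 128.0 * dynamic_viscosity * length / (math.pi * diameter ** 4)


def davies_permeability(fiber_radius: float, fibrin_fraction: float) -> float:
    """Davies permeability R_f^2 / (16 Phi_f^1.5 (1 + 56 Phi_f^3)) of a
    fibrous medium, in m^2.

    An empirical correlation for flow through random fibre beds, validated
    for fibrin clots; ``fibrin_fraction`` is the solid (fibre) volume
    fraction Phi_f in (0, 1).
    """
    if fiber_radius <= 0:
        raise ValueError("fiber_radius must be positive")
    if not 0.0 < fibrin_fraction < 1.0:
        raise ValueError("fibrin_fraction must lie in (0, 1)")
    phi = fibrin_fraction
    return fiber_radius ** 2 / (16.0 * phi ** 1.5 * (1.0 + 56.0 * phi ** 3))


def clot_darcy_resistance(permeability: float, clot_length: float,
                          lumen_area: float, dynamic_viscosity: float) -> float:
    """Lumped Darcy resistance mu*L/(k*A) of a porous clot plug, Pa.s/m^3.

    Superficial-velocity convention: the resistance relates the volumetric
    flow rate through the plug to the pressure drop across it
    (Delta P = mu L Q / (k A)); ``permeability = inf`` is the patent-vessel
    limit and returns 0.
    """
    if clot_length <= 0 or lumen_area <= 0 or dynamic_viscosity <= 0:
        raise ValueError("clot_length, lumen_area and viscosity must be positive")
    if not permeability > 0:
        raise ValueError("permeability must be positive")
    return dynamic_viscosity * clot_length / (permeability * lumen_area)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as incompressible and Newtonian.

    Defaults are average large-vessel blood properties: density
    1060 kg/m^3, kinematic viscosity 3.77e-6 m^2/s (3.77 cSt).  The dynamic
    viscosity is derived as rho*nu (~4e-3 Pa.s).
    """

    density: float = 1060.0
    kinematic_viscosity: float = 3.77e-6

    def __post_init__(self) -> None:
        if self.density <= 0 or self.kinematic_viscosity <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def dynamic_viscosity(self) -> float:
        return self.density * self.kinematic_viscosity


@dataclass
class VesselSegment:
    """A straight resistive vessel element between two pressure nodes.

    ``resistance`` is Hagen-Poiseuille from (length, diameter, mu) unless an
    explicit override is supplied (used for the clot element, whose
    resistance is Darcy, not Poiseuille).
    """

    id: str
    name: str
    from_node: str
    to_node: str
    length: float
    diameter: float
    resistance: float = 0.0  # filled in __post_init__ when not overridden
    viscosity: float = FluidProperties().dynamic_viscosity

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(f"segment {self.id}: non-positive geometry")
        if self.resistance == 0.0:
            self.resistance = hagen_poiseuille_resistance(
                self.length, self.diameter, self.viscosity)
        if self.resistance <= 0:
            raise ValueError(f"segment {self.id}: non-positive resistance")


class CollateralScore(Enum):
    """Collateral development level: absent (CS0) to extra-large (CS4)."""

    CS0 = 0
    CS1 = 1
    CS2 = 2
    CS3 = 3
    CS4 = 4


#: default lumped collateral geometry per score: (length m, diameter m)
COLLATERAL_GEOMETRY = {
    CollateralScore.CS1: (35.5e-3, 0.75e-3),
    CollateralScore.CS2: (35.5e-3, 1.00e-3),
    CollateralScore.CS3: (34.8e-3, 1.25e-3),
    CollateralScore.CS4: (34.8e-3, 1.50e-3),
}


@dataclass(frozen=True)
class CollateralModel:
    """Single-resistor surrogate for one hemisphere's leptomeningeal network.

    CS0 means the element is absent (infinite resistance); it is represented
    by *absence* of the segment, never by a large finite resistor.
    """

    score: CollateralScore
    length: float = 0.0
    diameter: float = 0.0
    viscosity: float = FluidProperties().dynamic_viscosity

    @classmethod
    def from_score(cls, score: CollateralScore,
                   viscosity: float | None = None,
                   geometry: dict | None = None) -> "CollateralModel":
        mu = viscosity if viscosity is not None else FluidProperties().dynamic_viscosity
        if score is CollateralScore.CS0:
            return cls(score=score, viscosity=mu)
        table = geometry or COLLATERAL_GEOMETRY
        length, diameter = table[score]
        return cls(score=score, length=length, diameter=diameter, viscosity=mu)

    @property
    def present(self) -> bool:
        return self.score is not CollateralScore.CS0

    @property
    def resistance(self) -> float:
        """Pa.s/m^3; infinite for the absent (CS0) collateral."""
        if not self.present:
            return math.inf
        return hagen_poiseuille_resistance(self.length, self.diameter,
                                           self.viscosity)


@dataclass(frozen=True)
class ClotModel:
    """Fibrous-clot microstructure and its lumped hydraulic description.

    Defaults: fibrin fibre radius 250 nm, fibrin volume fraction 0.18
    (permeability 0.0386 um^2 via Davies), 5 mm plug in the proximal
    M1-LMCA; the effective lumen area is the mean of the proximal and
    distal clot-face areas (7.40 and 6.38 mm^2).
    """

    fiber_radius: float = 250e-9
    fibrin_fraction: float = 0.18
    clot_length: float = 5e-3
    face_area_proximal: float = 7.40e-6
    face_area_distal: float = 6.38e-6

    def __post_init__(self) -> None:
        if self.fiber_radius <= 0 or self.clot_length <= 0:
            raise ValueError("clot geometry must be positive")
        if not 0.0 < self.fibrin_fraction < 1.0:
            raise ValueError("fibrin_fraction must lie in (0, 1)")
        if self.face_area_proximal <= 0 or self.face_area_distal <= 0:
            raise ValueError("clot face areas must be positive")

    @property
    def porosity(self) -> float:
        """Fluid volume fraction Phi = 1 - Phi_f (saturated medium)."""
        return 1.0 - self.fibrin_fraction

    @property
    def lumen_area(self) -> float:
        return 0.5 * (self.face_area_proximal + self.face_area_distal)

    @property
    def permeability(self) -> float:
        return davies_permeability(self.fiber_radius, self.fibrin_fraction)

    def darcy_resistance(self, dynamic_viscosity: float) -> float:
        return clot_darcy_resistance(self.permeability, self.clot_length,
                                     self.lumen_area, dynamic_viscosity)


@dataclass
class CoWNetwork:
    """Validated lumped Circle-of-Willis network.

    Attributes
    ----------
    segments : list of VesselSegment
        All resistive elements, including collateral and clot elements.
    inlets / outlets : dict
        Boundary name -> attachment node.  Inlets carry prescribed flow,
        outlets attach three-element Windkessel boundaries.
    collateral : CollateralModel
        Lumped collateral description (shared by both hemispheres).
    collateral_segment_ids : dict
        'ipsilateral'/'contralateral' -> segment id (oriented ACA -> MCA so
        retrograde recruitment is a positive flow), empty for CS0.
    clot : ClotModel or None
        Present iff the network is occluded; the clot element replaces the
        mid M1-LMCA sub-segment, leaving probe nodes on both faces.
    """

    segments: list
    inlets: dict
    outlets: dict
    fluid: FluidProperties
    collateral: CollateralModel
    collateral_segment_ids: dict = field(default_factory=dict)
    clot: ClotModel | None = None
    clot_segment_id: str | None = None

    @property
    def nodes(self) -> set:
        out: set = set()
        for seg in self.segments:
            out.add(seg.from_node)
            out.add(seg.to_node)
        return out

    @property
    def occluded(self) -> bool:
        return self.clot is not None

    def segment(self, segment_id: str) -> VesselSegment:
        for seg in self.segments:
            if seg.id == segment_id:
                return seg
        raise KeyError(segment_id)

    @property
    def clot_probe_nodes(self) -> tuple | None:
        """(proximal, distal) nodes adjacent to the clot faces, if occluded."""
        if self.clot_segment_id is None:
            return None
        seg = self.segment(self.clot_segment_id)
        return seg.from_node, seg.to_node

    def validate(self) -> None:
        ids = [seg.id for seg in self.segments]
        if len(ids) != len(set(ids)):
            raise NetworkConfigError("duplicate segment ids")
        if len(self.inlets) != 3:
            raise NetworkConfigError("expected exactly 3 inlets")
        if len(self.outlets) != 8:
            raise NetworkConfigError("expected exactly 8 outlets")
        g = nx.Graph()
        for seg in self.segments:
            g.add_edge(seg.from_node, seg.to_node)
        for node in list(self.inlets.values()) + list(self.outlets.values()):
            if node not in g:
                raise NetworkConfigError(f"boundary node {node!r} not in graph")
        if not nx.is_connected(g):
            raise NetworkConfigError("network graph is not connected")
        names = {seg.name for seg in self.segments}
        for comm in ("AComA", "LPComA", "RPComA"):
            if comm not in names:
                raise NetworkConfigError(f"missing communicating artery {comm}")


# ---------------------------------------------------------------------------
# configuration and assembly
# ---------------------------------------------------------------------------

def default_network_config() -> dict:
    """The shipped CoW description (geometry, clot, Windkessel, targets)."""
    text = resources.files("willisflow.data").joinpath(
        "cow_default.yaml").read_text()
    return yaml.safe_load(text)


def load_network_config(path: str | Path | None = None) -> dict:
    if path is None:
        return default_network_config()
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "segments" not in cfg:
        raise NetworkConfigError(f"{path}: not a network description")
    return cfg


def build_network(collateral_score: CollateralScore | str = CollateralScore.CS0,
                  occluded: bool = False,
                  config: dict | str | Path | None = None) -> CoWNetwork:
    """Assemble a validated CoWNetwork from a network description.

    ``collateral_score`` selects the lumped collateral calibre (CS0 = no
    collateral elements).  ``occluded`` replaces the mid sub-segment of the
    proximal M1-LMCA with the porous-clot Darcy element, so the nodes on
    either side of it act as the clot-face pressure probes.
    """
    if isinstance(collateral_score, str):
        collateral_score = CollateralScore[collateral_score]
    if config is None or isinstance(config, (str, Path)):
        config = load_network_config(config)

    fluid = FluidProperties(
        density=float(config["fluid"]["density_kg_m3"]),
        kinematic_viscosity=float(config["fluid"]["kinematic_viscosity_m2_s"]),
    )
    mu = fluid.dynamic_viscosity

    segments: list[VesselSegment] = []
    for entry in config["segments"]:
        seg = VesselSegment(
            id=entry.get("id", entry["name"]),
            name=entry["name"],
            from_node=entry["from"],
            to_node=entry["to"],
            length=float(entry["length_mm"]) * 1e-3,
            diameter=float(entry["diameter_mm"]) * 1e-3,
            resistance=float(entry.get("resistance_override", 0.0)),
            viscosity=mu,
        )
        segments.append(seg)

    geometry = None
    coll_cfg = config.get("collateral", {})
    if "geometry" in coll_cfg:
        geometry = {
            CollateralScore[score]: (float(g["length_mm"]) * 1e-3,
                                     float(g["diameter_mm"]) * 1e-3)
            for score, g in coll_cfg["geometry"].items()
        }
    collateral = CollateralModel.from_score(collateral_score, viscosity=mu,
                                            geometry=geometry)
    collateral_segment_ids: dict = {}
    if collateral.present:
        for side in ("ipsilateral", "contralateral"):
            attach = coll_cfg["attach"][side]
            seg_id = f"collateral_{side}"
            segments.append(VesselSegment(
                id=seg_id, name=f"LCN-{side}",
                from_node=attach["from"], to_node=attach["to"],
                length=collateral.length, diameter=collateral.diameter,
                viscosity=mu,
            ))
            collateral_segment_ids[side] = seg_id

    clot = None
    clot_segment_id = None
    if occluded:
        clot_cfg = config["clot"]
        clot = ClotModel(
            fiber_radius=float(clot_cfg["fiber_radius_nm"]) * 1e-9,
            fibrin_fraction=float(clot_cfg["fibrin_fraction"]),
            clot_length=float(clot_cfg["length_mm"]) * 1e-3,
            face_area_proximal=float(clot_cfg["face_area_proximal_mm2"]) * 1e-6,
            face_area_distal=float(clot_cfg["face_area_distal_mm2"]) * 1e-6,
        )
        target = clot_cfg["segment"]
        try:
            host = next(s for s in segments if s.id == target)
        except StopIteration:
            raise NetworkConfigError(f"clot host segment {target!r} missing")
        # the clot plug replaces the host sub-segment's Poiseuille resistance
        host.resistance = clot.darcy_resistance(mu)
        host.name = f"{host.name}-clot"
        clot_segment_id = host.id

    network = CoWNetwork(
        segments=segments,
        inlets=dict(config["inlets"]),
        outlets=dict(config["outlets"]),
        fluid=fluid,
        collateral=collateral,
        collateral_segment_ids=collateral_segment_ids,
        clot=clot,
        clot_segment_id=clot_segment_id,
    )
    network.validate()
    return network
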