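"""Transient 0D solver for the lumped CoW network.

Each time step solves the resistive network (Kirchhoff current law with
prescribed inlet flows and three-element Windkessel outlets) and then
advances the Windkessel compliance states.  All dynamics live in the outlet
compliances: vessel segments carry neither inertance nor distributed
compliance, so the solved quantities are the resistive/RCR-dominated ones
(mean flows, mean and formula arterial pressures), while pulse-pressure
fine structure is approximate by construction.

The Windkessel ODE C dP_c/dt = Q - (P_c - P_ref)/R2 is advanced with the
exact integrating-factor (exponential) update under a per-step constant Q,
which is unconditionally stable for the stiff R2*C products that occur
here at the default 1 ms step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from . import analysis
from .units import PA_PER_MMHG
from .waveforms import FlowWaveform

__all__ = [
    "WindkesselBC",
    "SimulationConfig",
    "SimulationResult",
    "windkessel_update",
    "solve_network_step",
    "run",
    "default_windkessels",
    "TopologyError",
]


class TopologyError(ValueError):
    """Raised when the resistive system is singular (e.g. isolated node)."""


@dataclass
class WindkesselBC:
    """Three-element (RCR) Windkessel outlet.

    ``R1`` is the proximal (characteristic) resistance in series with the
    parallel pair of distal resistance ``R2`` and compliance ``C``;
    ``state_pressure`` is the pressure across C and ``reference_pressure``
    the distal venous pressure (default 0 Pa).
    """

    R1: float
    R2: float
    C: float
    state_pressure: float = 0.0
    reference_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R2 <= 0 or self.C <= 0:
            raise ValueError("R1, R2 and C must be positive")

    def advance(self, inflow: float, dt: float) -> None:
        """Exact exponential update of the compliance state over dt with the
        inflow held constant."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        target = self.reference_pressure + inflow * self.R2
        decay = math.exp(-dt / (self.R2 * self.C))
        self.state_pressure = target + (self.state_pressure - target) * decay

    def boundary_pressure(self, inflow: float) -> float:
        return self.state_pressure + inflow * self.R1


def windkessel_update(bc: WindkesselBC, inflow: float, dt: float) -> float:
    """Advance ``bc`` one step and return the boundary pressure
    P = P_c + Q*R1 at the new state."""
    bc.advance(inflow, dt)
    return bc.boundary_pressure(inflow)


def default_windkessels(config: dict) -> dict:
    """Windkessel set from a network description's ``windkessel`` block."""
    return {
        name: WindkesselBC(R1=float(p["R1"]), R2=float(p["R2"]),
                           C=float(p["C"]))
        for name, p in config["windkessel"].items()
    }


@dataclass
class SimulationConfig:
    """Time-marching protocol: 6 s at dt = 1 ms covers 7 complete 857 ms
    cardiac cycles; the first two cycles are discarded from analysis to
    remove the Windkessel initialisation transient."""

    dt: float = 1e-3
    duration: float = 6.0
    period: float = 0.857
    n_discard_cycles: int = 2

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.period <= 0:
            raise ValueError("dt and period must be positive")
        if self.duration < 3 * self.period:
            raise ValueError("duration must cover at least 3 cardiac cycles")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def steps_per_cycle(self) -> int:
        return int(round(self.period / self.dt))

    @property
    def n_analyzed_cycles(self) -> int:
        total = int(math.floor(self.duration / self.period + 1e-9))
        return total - self.n_discard_cycles


# ---------------------------------------------------------------------------
# linear network solve
# ---------------------------------------------------------------------------

def _check_conditioning(a: np.ndarray) -> None:
    """Reject (numerically) singular systems, e.g. nodes with no path to a
    pressure reference; a zero RHS can otherwise mask exact singularity."""
    if a.size == 0:
        raise TopologyError("no free nodes to solve for")
    if not np.all(np.isfinite(a)) or np.linalg.cond(a) > 1e12:
        raise TopologyError("singular resistive system (isolated node or "
                            "missing pressure reference)")


def _boundary_nodes(network, flows_or_pressures: dict, boundary_map: dict) -> dict:
    """Map boundary names (or raw node labels) onto node labels."""
    out = {}
    for key, value in flows_or_pressures.items():
        out[boundary_map.get(key, key)] = value
    return out


def solve_network_step(network, inlet_flows: dict, outlet_pressures: dict):
    """Single steady resistive solve: KCL at every free node.

    ``inlet_flows`` (m^3/s, injected) and ``outlet_pressures`` (Pa,
    Dirichlet) are keyed by boundary name or directly by node label.
    Returns ``(pressures, flows)``: node label -> Pa, and segment id ->
    m^3/s with the positive direction from_node -> to_node.
    """
    segments = network.segments
    inlet_by_node = _boundary_nodes(network, inlet_flows,
                                    getattr(network, "inlets", {}))
    fixed_by_node = _boundary_nodes(network, outlet_pressures,
                                    getattr(network, "outlets", {}))
    if not fixed_by_node:
        raise TopologyError("at least one pressure-referenced boundary needed")

    nodes = sorted({seg.from_node for seg in segments}
                   | {seg.to_node for seg in segments})
    free = [n for n in nodes if n not in fixed_by_node]
    index = {n: i for i, n in enumerate(free)}

    a = np.zeros((len(free), len(free)))
    b = np.zeros(len(free))
    for seg in segments:
        g = 1.0 / seg.resistance
        for here, there in ((seg.from_node, seg.to_node),
                            (seg.to_node, seg.from_node)):
            if here in index:
                i = index[here]
                a[i, i] += g
                if there in index:
                    a[i, index[there]] -= g
                else:
                    b[i] += g * fixed_by_node[there]
    for node, q in inlet_by_node.items():
        if node in index:
            b[index[node]] += q

    _check_conditioning(a)
    try:
        x = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise TopologyError(f"singular resistive system: {exc}") from exc

    pressures = dict(fixed_by_node)
    pressures.update({n: float(x[i]) for n, i in index.items()})
    flows = {seg.id: (pressures[seg.from_node] - pressures[seg.to_node])
             / seg.resistance for seg in segments}
    return pressures, flows


class _AssembledNetwork:
    """Constant-resistance network pre-factorised for repeated solves.

    All network nodes are unknowns; each Windkessel outlet couples its
    attachment node through 1/R1 to the (known) compliance-state pressure,
    so one LU factorisation serves every time step.
    """

    def __init__(self, network, windkessels: dict):
        self.network = network
        self.windkessels = windkessels
        self.nodes = sorted(network.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.outlet_items = sorted(network.outlets.items())
        self.inlet_items = sorted(network.inlets.items())
        n = len(self.nodes)
        a = np.zeros((n, n))
        for seg in network.segments:
            g = 1.0 / seg.resistance
            i, j = self.index[seg.from_node], self.index[seg.to_node]
            a[i, i] += g
            a[j, j] += g
            a[i, j] -= g
            a[j, i] -= g
        for name, node in self.outlet_items:
            a[self.index[node], self.index[node]] += 1.0 / windkessels[name].R1
        _check_conditioning(a)
        self.lu = lu_factor(a)

    def solve(self, inlet_flows: dict) -> tuple:
        """Node pressures and per-outlet boundary flows for the current
        Windkessel states."""
        b = np.zeros(len(self.nodes))
        for name, node in self.inlet_items:
            b[self.index[node]] += inlet_flows[name]
        for name, node in self.outlet_items:
            bc = self.windkessels[name]
            b[self.index[node]] += bc.state_pressure / bc.R1
        p = lu_solve(self.lu, b)
        outlet_flows = {
            name: (p[self.index[node]] - self.windkessels[name].state_pressure)
            / self.windkessels[name].R1
            for name, node in self.outlet_items
        }
        return p, outlet_flows

    def steady_initialise(self, mean_inlet_flows: dict) -> None:
        """Set each compliance state to its periodic-mean operating point,
        P_ref + Q*R2, from a steady solve with R1+R2 outlet loads."""
        segments = list(self.network.segments)
        ghosts = {}
        for name, node in self.outlet_items:
            bc = self.windkessels[name]
            ghost = f"__ref_{name}"
            segments.append(_Resistor(f"__wk_{name}", node, ghost,
                                      bc.R1 + bc.R2))
            ghosts[ghost] = bc.reference_pressure
        shim = _SegmentsOnly(segments)
        pressures, flows = solve_network_step(shim, {
            self.network.inlets[name]: q
            for name, q in mean_inlet_flows.items()
        }, ghosts)
        for name, node in self.outlet_items:
            bc = self.windkessels[name]
            q = flows[f"__wk_{name}"]
            bc.state_pressure = bc.reference_pressure + q * bc.R2


@dataclass(frozen=True)
class _Resistor:
    id: str
    from_node: str
    to_node: str
    resistance: float


class _SegmentsOnly:
    def __init__(self, segments):
        self.segments = segments


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Pressure/flow time series at every boundary plus probe channels.

    ``pressures``/``flows`` map boundary name -> array over the full time
    grid (Pa, m^3/s).  ``collateral_flows`` holds the ipsi/contralateral
    lumped-collateral flows (positive ACA -> MCA, i.e. retrograde
    recruitment) and ``clot_pressures`` the node pressures immediately
    adjacent to the clot faces, when those elements exist.
    """

    time: np.ndarray
    pressures: dict
    flows: dict
    collateral_flows: dict
    clot_pressures: dict
    config: SimulationConfig
    inlet_names: tuple
    outlet_names: tuple
    mass_error_max: float = 0.0
    converged: bool = True
    warnings: list = field(default_factory=list)

    # -- cycle-aware views --------------------------------------------------
    def analysis_slice(self) -> slice:
        """Index window covering the analyzed integer cycles (after the
        discarded initial cycles)."""
        cfg = self.config
        i0 = int(round(cfg.n_discard_cycles * cfg.period / cfg.dt))
        i1 = i0 + cfg.n_analyzed_cycles * cfg.steps_per_cycle
        return slice(i0, min(i1, self.time.size - 1) + 1)

    def _window(self, series: np.ndarray) -> tuple:
        win = self.analysis_slice()
        return self.time[win], series[win]

    def mean_flow(self, boundary: str) -> float:
        """Trapezoidal mean flow (m^3/s) over the analyzed cycles."""
        t, q = self._window(self.flows[boundary])
        return analysis.mean_flow(t, q)

    def mean_collateral_flow(self, side: str) -> float:
        t, q = self._window(self.collateral_flows[side])
        return analysis.mean_flow(t, q)

    def pressure_extrema(self, boundary: str) -> tuple:
        t, p = self._window(self.pressures[boundary])
        return float(p.min()), float(p.max())

    def map_pressure(self, boundary: str) -> float:
        """Formula MAP = (2*dia + sys)/3 over the analyzed window, Pa."""
        dia, sys = self.pressure_extrema(boundary)
        return analysis.map_calc(dia, sys)

    def time_mean_pressure(self, boundary: str) -> float:
        t, p = self._window(self.pressures[boundary])
        return analysis.mean_flow(t, p)  # same trapezoidal time average

    def systemic_pressures(self) -> tuple:
        """(sSBP, sDBP, systemic MAP) in Pa from the three inlet traces."""
        traces = [self._window(self.pressures[n])[1] for n in self.inlet_names]
        return analysis.systemic_pressures(traces)

    def clot_pressure_summary(self) -> dict | None:
        """MAPs adjacent to the clot faces plus the mean pressure drop in
        both conventions (difference of MAPs vs time-averaged drop), Pa."""
        if not self.clot_pressures:
            return None
        t, p_prox = self._window(self.clot_pressures["proximal"])
        _, p_dist = self._window(self.clot_pressures["distal"])
        map_prox = analysis.map_calc(float(p_prox.min()), float(p_prox.max()))
        map_dist = analysis.map_calc(float(p_dist.min()), float(p_dist.max()))
        return {
            "map_proximal": map_prox,
            "map_distal": map_dist,
            "sys_proximal": float(p_prox.max()),
            "sys_distal": float(p_dist.max()),
            "delta_p_map": map_prox - map_dist,
            "delta_p_time_mean": analysis.mean_flow(t, p_prox - p_dist),
        }

    def summary(self):
        """Tidy per-boundary summary DataFrame in clinical units."""
        import pandas as pd

        from .units import m3s_to_mlmin, pa_to_mmhg
        rows = []
        for kind, names in (("inlet", self.inlet_names),
                            ("outlet", self.outlet_names)):
            for name in names:
                dia, sys = self.pressure_extrema(name)
                rows.append({
                    "boundary": name,
                    "kind": kind,
                    "mean_flow_ml_min": m3s_to_mlmin(self.mean_flow(name)),
                    "map_mmhg": pa_to_mmhg(analysis.map_calc(dia, sys)),
                    "systolic_mmhg": pa_to_mmhg(sys),
                    "diastolic_mmhg": pa_to_mmhg(dia),
                })
        return pd.DataFrame(rows)

    def cycle_map_drift(self) -> float:
        """Largest relative cycle-to-cycle change in any boundary MAP over
        the analyzed cycles (periodic steady-state measure)."""
        cfg = self.config
        spc = cfg.steps_per_cycle
        i0 = int(round(cfg.n_discard_cycles * cfg.period / cfg.dt))
        drift = 0.0
        floor = 1.0 * PA_PER_MMHG  # avoid 0/0 on near-zero occluded MAPs
        for name in (*self.inlet_names, *self.outlet_names):
            p = self.pressures[name]
            maps = []
            for c in range(cfg.n_analyzed_cycles):
                chunk = p[i0 + c * spc: i0 + (c + 1) * spc + 1]
                maps.append(analysis.map_calc(float(chunk.min()),
                                              float(chunk.max())))
            for a, b in zip(maps, maps[1:]):
                drift = max(drift, abs(b - a) / max(abs(a), floor))
        return drift


# ---------------------------------------------------------------------------
# time marching
# ---------------------------------------------------------------------------

def run(network, inlet_waveforms: dict, config: SimulationConfig | None = None,
        windkessels: dict | None = None,
        initial_state: str = "steady") -> SimulationResult:
    """Time-march the pulsatile 0D simulation.

    ``inlet_waveforms`` maps each inlet name to a FlowWaveform whose period
    equals ``config.period``.  ``windkessels`` maps each outlet name to its
    WindkesselBC (states are (re)initialised here: ``initial_state`` is
    "steady" for the periodic-mean operating point or "zero").  A
    non-convergent periodic state is flagged in ``result.warnings``.
    """
    if config is None:
        config = SimulationConfig()
    if windkessels is None:
        raise ValueError("windkessels must be supplied (one per outlet)")
    for name in network.inlets:
        if name not in inlet_waveforms:
            raise ValueError(f"missing inlet waveform for {name}")
        wf: FlowWaveform = inlet_waveforms[name]
        if not math.isclose(wf.period, config.period, rel_tol=1e-9):
            raise ValueError(
                f"waveform period {wf.period} != simulation period "
                f"{config.period} for inlet {name}")
    for name in network.outlets:
        if name not in windkessels:
            raise ValueError(f"missing Windkessel for outlet {name}")

    assembled = _AssembledNetwork(network, windkessels)
    n_steps = config.n_steps
    time = np.arange(n_steps + 1) * config.dt

    inlet_series = {name: inlet_waveforms[name].sample(time)
                    for name in network.inlets}
    if initial_state == "steady":
        assembled.steady_initialise(
            {name: inlet_waveforms[name].mean_flow for name in network.inlets})
    elif initial_state == "zero":
        for bc in windkessels.values():
            bc.state_pressure = bc.reference_pressure
    else:
        raise ValueError(f"unknown initial_state {initial_state!r}")

    inlet_names = tuple(sorted(network.inlets))
    outlet_names = tuple(sorted(network.outlets))
    pressures = {n: np.empty(n_steps + 1)
                 for n in (*inlet_names, *outlet_names)}
    flows = {n: np.empty(n_steps + 1) for n in (*inlet_names, *outlet_names)}
    collateral_flows = {side: np.empty(n_steps + 1)
                        for side in network.collateral_segment_ids}
    clot_nodes = network.clot_probe_nodes
    clot_pressures = ({"proximal": np.empty(n_steps + 1),
                       "distal": np.empty(n_steps + 1)}
                      if clot_nodes else {})
    coll_segs = {side: network.segment(seg_id)
                 for side, seg_id in network.collateral_segment_ids.items()}

    node_index = assembled.index
    mass_error_max = 0.0
    for k in range(n_steps + 1):
        q_in = {name: inlet_series[name][k] for name in inlet_names}
        p, q_out = assembled.solve(q_in)
        for name in inlet_names:
            pressures[name][k] = p[node_index[network.inlets[name]]]
            flows[name][k] = q_in[name]
        for name in outlet_names:
            pressures[name][k] = p[node_index[network.outlets[name]]]
            flows[name][k] = q_out[name]
        for side, seg in coll_segs.items():
            collateral_flows[side][k] = (
                p[node_index[seg.from_node]] - p[node_index[seg.to_node]]
            ) / seg.resistance
        if clot_nodes:
            clot_pressures["proximal"][k] = p[node_index[clot_nodes[0]]]
            clot_pressures["distal"][k] = p[node_index[clot_nodes[1]]]
        total_in = sum(q_in.values())
        total_out = sum(q_out.values())
        if total_in != 0.0:
            mass_error_max = max(mass_error_max,
                                 abs(total_in - total_out) / abs(total_in))
        if k < n_steps:
            for name in outlet_names:
                windkessels[name].advance(q_out[name], config.dt)

    result = SimulationResult(
        time=time, pressures=pressures, flows=flows,
        collateral_flows=collateral_flows, clot_pressures=clot_pressures,
        config=config, inlet_names=inlet_names, outlet_names=outlet_names,
        mass_error_max=mass_error_max,
    )
    drift = result.cycle_map_drift()
    if drift >= 0.005:
        result.converged = False
        result.warnings.append(
            f"periodic state not reached: cycle-to-cycle MAP drift "
            f"{drift:.3%} >= 0.5%")
    return result
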