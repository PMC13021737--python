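"""Windkessel dynamics, resistive network solves, and the transient run."""

import copy
import math

import numpy as np
import pytest

from willisflow.network import (
    CollateralModel,
    CollateralScore,
    CoWNetwork,
    FluidProperties,
    build_network,
    hagen_poiseuille_resistance,
)
from willisflow.simulator import (
    SimulationConfig,
    TopologyError,
    WindkesselBC,
    _Resistor,
    _SegmentsOnly,
    run,
    solve_network_step,
    windkessel_update,
)
from willisflow.units import m3s_to_mlmin
from willisflow.waveforms import FlowWaveform


def toy_network(segments, inlets, outlets):
    """Minimal network wrapper reusing the CoW container (unvalidated)."""
    return CoWNetwork(segments=segments, inlets=inlets, outlets=outlets,
                      fluid=FluidProperties(),
                      collateral=CollateralModel.from_score(
                          CollateralScore.CS0))


class TestWindkessel:
    def test_steady_state_constant_inflow(self):
        bc = WindkesselBC(R1=3e8, R2=5e9, C=6e-11, state_pressure=0.0)
        q = 2.4e-6
        for _ in range(int(50 * bc.R2 * bc.C / 1e-3)):
            bc.advance(q, 1e-3)
        assert bc.boundary_pressure(q) == pytest.approx(q * (bc.R1 + bc.R2),
                                                        rel=1e-9)

    def test_zero_inflow_exponential_decay(self):
        p0, pref = 1.2e4, 4.0e2
        bc = WindkesselBC(R1=3e8, R2=5e9, C=6e-11, state_pressure=p0,
                          reference_pressure=pref)
        tau = bc.R2 * bc.C
        n = 1000
        for _ in range(n):
            bc.advance(0.0, tau / n)
        # after exactly one time constant the excess has decayed by 1/e
        assert bc.state_pressure == pytest.approx(
            pref + (p0 - pref) / math.e, rel=1e-12)

    def test_linear_ramp_local_error_second_order(self):
        """One-step error vs the integrating-factor analytic solution for
        Q(t) = Q0 + a*t shrinks ~4x when dt is halved."""
        r2, c, pref = 5e9, 6e-11, 0.0
        q0, a = 1e-6, 2e-4
        p0 = 3e3
        tau = r2 * c

        def analytic(t):
            return (pref + r2 * (q0 + a * t) - a * r2 * tau
                    + math.exp(-t / tau) * (p0 - pref - r2 * q0
                                            + a * r2 * tau))

        errors = []
        for dt in (2e-3, 1e-3):
            bc = WindkesselBC(R1=3e8, R2=r2, C=c, state_pressure=p0,
                              reference_pressure=pref)
            bc.advance(q0, dt)  # Q frozen at the left endpoint
            errors.append(abs(bc.state_pressure - analytic(dt)))
        ratio = errors[0] / errors[1]
        assert 3.5 < ratio < 4.5

    def test_update_returns_boundary_pressure(self):
        bc = WindkesselBC(R1=3e8, R2=5e9, C=6e-11, state_pressure=1e4)
        q = 1e-6
        p = windkessel_update(bc, q, 1e-3)
        assert p == pytest.approx(bc.state_pressure + q * bc.R1, rel=1e-14)


class TestSolveNetworkStep:
    def test_series_circuit(self):
        """Flow source Q through R_a then R_b to ground: mid node at Q*R_b."""
        ra, rb, q = 2e9, 5e9, 1.5e-6
        net = toy_network(
            [_Resistor("a", "in", "mid", ra), _Resistor("b", "mid", "gnd", rb)],
            inlets={"IN": "in"}, outlets={"OUT": "gnd"})
        pressures, flows = solve_network_step(net, {"IN": q}, {"OUT": 0.0})
        assert pressures["mid"] == pytest.approx(q * rb, rel=1e-12)
        assert flows["a"] == pytest.approx(q, rel=1e-10)
        assert flows["b"] == pytest.approx(q, rel=1e-10)

    def test_y_network_matches_dense_oracle(self):
        """3-branch star: compare with an independent dense Laplacian solve."""
        rs = {"a": 1.7e9, "b": 3.1e9, "c": 8.3e8}
        q_in = 2.2e-6
        net = toy_network(
            [_Resistor("a", "n1", "hub", rs["a"]),
             _Resistor("b", "hub", "n2", rs["b"]),
             _Resistor("c", "hub", "n3", rs["c"])],
            inlets={"IN": "n1"}, outlets={"O2": "n2", "O3": "n3"})
        pressures, flows = solve_network_step(
            net, {"IN": q_in}, {"O2": 500.0, "O3": 0.0})

        # brute-force oracle: full Laplacian, Dirichlet rows replaced
        nodes = ["n1", "hub", "n2", "n3"]
        idx = {n: i for i, n in enumerate(nodes)}
        lap = np.zeros((4, 4))
        for sid, (u, v) in {"a": ("n1", "hub"), "b": ("hub", "n2"),
                            "c": ("hub", "n3")}.items():
            g = 1.0 / rs[sid]
            i, j = idx[u], idx[v]
            lap[i, i] += g
            lap[j, j] += g
            lap[i, j] -= g
            lap[j, i] -= g
        rhs = np.zeros(4)
        rhs[idx["n1"]] = q_in
        for node, val in (("n2", 500.0), ("n3", 0.0)):
            lap[idx[node]] = 0.0
            lap[idx[node], idx[node]] = 1.0
            rhs[idx[node]] = val
        expect = np.linalg.solve(lap, rhs)
        for node in nodes:
            assert pressures[node] == pytest.approx(expect[idx[node]],
                                                    rel=1e-10)
        # KCL at the free hub node
        assert (flows["a"] - flows["b"] - flows["c"]) == pytest.approx(
            0.0, abs=1e-10 * q_in)

    def test_resistance_scaling_linearity(self):
        segs = [_Resistor("a", "in", "mid", 2e9),
                _Resistor("b", "mid", "gnd", 5e9)]
        segs2 = [_Resistor(s.id, s.from_node, s.to_node, 2 * s.resistance)
                 for s in segs]
        q = {"in": 1e-6}
        p1, _ = solve_network_step(_SegmentsOnly(segs), q, {"gnd": 0.0})
        p2, _ = solve_network_step(_SegmentsOnly(segs2), q, {"gnd": 0.0})
        assert p2["mid"] == pytest.approx(2 * p1["mid"], rel=1e-12)
        assert p2["in"] == pytest.approx(2 * p1["in"], rel=1e-12)

    def test_isolated_component_is_singular(self):
        net = toy_network(
            [_Resistor("a", "in", "gnd", 1e9),
             _Resistor("b", "x", "y", 1e9)],  # floating island
            inlets={"IN": "in"}, outlets={"OUT": "gnd"})
        with pytest.raises(TopologyError):
            solve_network_step(net, {"IN": 1e-6}, {"OUT": 0.0})

    def test_requires_pressure_reference(self):
        net = toy_network([_Resistor("a", "in", "gnd", 1e9)],
                          inlets={"IN": "in"}, outlets={})
        with pytest.raises(TopologyError):
            solve_network_step(net, {"IN": 1e-6}, {})


class TestRun:
    def test_null_forcing_gives_reference_state(self, network_config):
        net = build_network(CollateralScore.CS0, occluded=False,
                            config=network_config)
        period = 0.857
        zero = FlowWaveform(times=np.linspace(0, period, 858),
                            flows=np.zeros(858), period=period)
        waves = {name: zero for name in net.inlets}
        wk = {name: WindkesselBC(R1=3e8, R2=5e9, C=6e-11)
              for name in net.outlets}
        config = SimulationConfig(dt=1e-3, duration=3.0, period=period,
                                  n_discard_cycles=1)
        result = run(net, waves, config, windkessels=wk,
                     initial_state="zero")
        for name in (*result.inlet_names, *result.outlet_names):
            assert np.allclose(result.pressures[name], 0.0, atol=1e-12)
            assert np.allclose(result.flows[name], 0.0, atol=1e-15)

    def test_mass_conservation(self, baseline_cs0, occluded_cs0):
        assert baseline_cs0.mass_error_max < 1e-8
        assert occluded_cs0.mass_error_max < 1e-8

    def test_periodic_steady_state_within_discard_window(self, baseline_cs0,
                                                         occluded_cs0):
        """Cycle-to-cycle MAP drift < 0.5% in every boundary after the two
        discarded cycles."""
        assert baseline_cs0.converged
        assert baseline_cs0.cycle_map_drift() < 0.005
        assert occluded_cs0.converged
        assert occluded_cs0.cycle_map_drift() < 0.005

    def test_occlusion_suppresses_lmca_flow(self, baseline_cs0, occluded_cs0):
        q_base = m3s_to_mlmin(baseline_cs0.mean_flow("LMCA"))
        q_occ = m3s_to_mlmin(occluded_cs0.mean_flow("LMCA"))
        assert q_occ < 1e-3 * q_base  # > 99.9% flow reduction

    def test_clot_probe_pressures_recorded(self, occluded_cs0):
        clot = occluded_cs0.clot_pressure_summary()
        assert clot is not None
        assert clot["map_proximal"] > clot["map_distal"]
        # distal MCA bed is nearly unperfused without collaterals
        assert clot["map_distal"] < 0.01 * clot["map_proximal"]

    def test_removing_clot_recovers_baseline_bitwise(
            self, network_config, sim_config, inlet_waveforms,
            calibration_cs0):
        """Restoring the host segment's Poiseuille resistance makes the
        occluded network's solution identical to the baseline's."""
        wk_a = copy.deepcopy(calibration_cs0.windkessels)
        wk_b = copy.deepcopy(calibration_cs0.windkessels)
        baseline = build_network(CollateralScore.CS0, occluded=False,
                                 config=network_config)
        occluded = build_network(CollateralScore.CS0, occluded=True,
                                 config=network_config)
        host = occluded.segment(occluded.clot_segment_id)
        host.resistance = hagen_poiseuille_resistance(
            host.length, host.diameter, occluded.fluid.dynamic_viscosity)
        res_a = run(baseline, inlet_waveforms, sim_config, windkessels=wk_a)
        res_b = run(occluded, inlet_waveforms, sim_config, windkessels=wk_b)
        for name in res_a.pressures:
            assert np.array_equal(res_a.pressures[name],
                                  res_b.pressures[name])
            assert np.array_equal(res_a.flows[name], res_b.flows[name])

    def test_waveform_period_mismatch_rejected(self, network_config,
                                               inlet_waveforms,
                                               calibration_cs0):
        net = build_network(CollateralScore.CS0, occluded=False,
                            config=network_config)
        config = SimulationConfig(period=0.9)
        with pytest.raises(ValueError):
            run(net, inlet_waveforms, config,
                windkessels=copy.deepcopy(calibration_cs0.windkessels))


class TestSimulationConfig:
    def test_protocol_counts(self):
        config = SimulationConfig()
        assert config.n_steps == 6000
        assert config.steps_per_cycle == 857
        assert config.n_analyzed_cycles == 5  # 7 cycles minus 2 discarded

    def test_duration_must_cover_three_cycles(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration=1.0)
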