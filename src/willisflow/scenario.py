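"""Scenario orchestration: waveforms -> calibration -> simulation -> tables.

This is the high-level pipeline behind the CLI and the examples: build (or
load) the inlet waveforms, calibrate the Windkessel outlets on the baseline
network, run the requested collateral-score / occlusion combination, and
flatten the result into tidy tables (the machine-readable analogues of the
per-boundary and clot-force summary tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .calibration import CalibrationResult, CalibrationTargets, calibrate
from .network import CollateralScore, build_network, load_network_config
from .simulator import SimulationConfig, SimulationResult, default_windkessels, run
from .units import m3s_to_mlmin, mlmin_to_m3s, pa_to_mmhg
from .waveforms import FlowWaveform, interpolate_waveform, scale_to_mean, synth_inlet_waveform

__all__ = [
    "ScenarioConfig",
    "make_inlet_waveforms",
    "load_inlet_waveforms_csv",
    "simulation_config_from",
    "run_scenario",
    "sweep",
    "timeseries_frame",
    "write_timeseries_csv",
]


@dataclass
class ScenarioConfig:
    """One simulation scenario.

    ``network_config`` is a network-description path (None for the shipped
    defaults); ``waveform_csv`` optionally replaces the synthetic inlet
    waveforms with sampled (time, flow) tables; ``seed`` controls the
    synthetic-waveform generator (shape jitter, default off, so runs are
    deterministic either way).
    """

    score: CollateralScore = CollateralScore.CS0
    occluded: bool = False
    network_config: str | Path | None = None
    waveform_csv: str | Path | None = None
    seed: int = 0
    calibrate_first: bool = True
    max_iter: int = 25
    output_dir: Path | None = None
    _config: dict = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if isinstance(self.score, str):
            self.score = CollateralScore[self.score]
        if self._config is None:
            self._config = load_network_config(self.network_config)

    @property
    def config(self) -> dict:
        return self._config


def simulation_config_from(config: dict) -> SimulationConfig:
    sim = config.get("simulation", {})
    return SimulationConfig(
        dt=float(sim.get("dt_s", 1e-3)),
        duration=float(sim.get("duration_s", 6.0)),
        period=float(sim.get("period_s", 0.857)),
        n_discard_cycles=int(sim.get("n_discard_cycles", 2)),
    )


def make_inlet_waveforms(config: dict, period: float, seed: int = 0,
                         dt: float = 1e-3) -> dict:
    """Synthetic PCMRI-like waveform per inlet, scaled to the configured
    mean inflow rates."""
    return {
        name: synth_inlet_waveform(name,
                                   mean_flow=mlmin_to_m3s(float(q_mlmin)),
                                   period=period, seed=seed, dt=dt)
        for name, q_mlmin in config["inflow_ml_min"].items()
    }


def load_inlet_waveforms_csv(path: str | Path, dt: float = 1e-3) -> dict:
    """Read inlet waveforms from a CSV with columns ``time_s`` and
    ``<inlet>_ml_min``; each column is spline-interpolated (periodic) onto
    the dt grid."""
    frame = pd.read_csv(path)
    if "time_s" not in frame.columns:
        raise ValueError(f"{path}: missing 'time_s' column")
    t = frame["time_s"].to_numpy(dtype=float)
    waves = {}
    for col in frame.columns:
        if not col.endswith("_ml_min"):
            continue
        name = col[: -len("_ml_min")]
        q = mlmin_to_m3s(frame[col].to_numpy(dtype=float))
        waves[name] = interpolate_waveform(np.column_stack([t, q]), dt=dt)
    if not waves:
        raise ValueError(f"{path}: no '<inlet>_ml_min' columns found")
    return waves


@dataclass
class ScenarioOutcome:
    """Everything a scenario produces, for reporting."""

    result: SimulationResult
    baseline_result: SimulationResult | None
    calibration: CalibrationResult | None
    windkessels: dict
    scenario: ScenarioConfig


def run_scenario(scenario: ScenarioConfig,
                 windkessels: dict | None = None,
                 with_baseline: bool = True) -> ScenarioOutcome:
    """Execute one scenario end to end.

    Calibration always happens on the baseline (non-occluded) network of
    the same collateral anatomy; the calibrated Windkessel set is then
    reused unchanged for the occluded run.  ``with_baseline`` also keeps
    the baseline result (needed for collateral recruitment metrics).
    """
    cfg = scenario.config
    sim_config = simulation_config_from(cfg)
    if scenario.waveform_csv is not None:
        waveforms = load_inlet_waveforms_csv(scenario.waveform_csv,
                                             dt=sim_config.dt)
    else:
        waveforms = make_inlet_waveforms(cfg, sim_config.period,
                                         seed=scenario.seed,
                                         dt=sim_config.dt)

    baseline = build_network(scenario.score, occluded=False, config=cfg)
    calibration = None
    if windkessels is None:
        windkessels = default_windkessels(cfg)
        if scenario.calibrate_first:
            calibration = calibrate(baseline,
                                    CalibrationTargets.from_config(cfg),
                                    waveforms, sim_config,
                                    windkessels=windkessels,
                                    max_iter=scenario.max_iter)
            windkessels = calibration.windkessels

    baseline_result = None
    if scenario.occluded:
        if with_baseline:
            baseline_result = (calibration.result if calibration is not None
                               else run(baseline, waveforms, sim_config,
                                        windkessels=windkessels))
        network = build_network(scenario.score, occluded=True, config=cfg)
        result = run(network, waveforms, sim_config, windkessels=windkessels)
    else:
        result = (calibration.result if calibration is not None
                  else run(baseline, waveforms, sim_config,
                           windkessels=windkessels))
    return ScenarioOutcome(result=result, baseline_result=baseline_result,
                           calibration=calibration, windkessels=windkessels,
                           scenario=scenario)


def _scenario_row(outcome: ScenarioOutcome) -> dict:
    """Flatten one scenario into a wide summary row (clinical units)."""
    result = outcome.result
    scenario = outcome.scenario
    row: dict = {"score": scenario.score.name,
                 "occluded": scenario.occluded}
    ssbp, sdbp, smap = result.systemic_pressures()
    row["systemic_systolic_mmhg"] = pa_to_mmhg(ssbp)
    row["systemic_diastolic_mmhg"] = pa_to_mmhg(sdbp)
    row["systemic_map_mmhg"] = pa_to_mmhg(smap)
    row["pulse_pressure_mmhg"] = pa_to_mmhg(ssbp - sdbp)
    for name in (*result.inlet_names, *result.outlet_names):
        row[f"flow_{name}_ml_min"] = m3s_to_mlmin(result.mean_flow(name))
        row[f"map_{name}_mmhg"] = pa_to_mmhg(result.map_pressure(name))
    for side in result.collateral_flows:
        row[f"collateral_{side}_ml_min"] = m3s_to_mlmin(
            result.mean_collateral_flow(side))

    clot = result.clot_pressure_summary()
    if clot is not None:
        row["clot_map_proximal_mmhg"] = pa_to_mmhg(clot["map_proximal"])
        row["clot_map_distal_mmhg"] = pa_to_mmhg(clot["map_distal"])
        row["clot_delta_p_map_mmhg"] = pa_to_mmhg(clot["delta_p_map"])
        row["clot_delta_p_time_mean_mmhg"] = pa_to_mmhg(
            clot["delta_p_time_mean"])
        clot_model = build_network(scenario.score, occluded=True,
                                   config=scenario.config).clot
        f_mean, f_max = analysis.compaction_forces(
            analysis.CompactionForceInputs(
                map_proximal_mmhg=pa_to_mmhg(clot["map_proximal"]),
                map_distal_mmhg=pa_to_mmhg(clot["map_distal"]),
                sys_proximal_mmhg=pa_to_mmhg(clot["sys_proximal"]),
                sys_distal_mmhg=pa_to_mmhg(clot["sys_distal"]),
                area_proximal=clot_model.face_area_proximal,
                area_distal=clot_model.face_area_distal,
            ))
        row["f_mean_mn"] = f_mean * 1e3
        row["f_max_mn"] = f_max * 1e3

    if (scenario.occluded and outcome.baseline_result is not None
            and result.collateral_flows):
        base = outcome.baseline_result
        metrics = analysis.collateral_metrics(
            m3s_to_mlmin(result.mean_collateral_flow("ipsilateral")),
            m3s_to_mlmin(base.mean_collateral_flow("ipsilateral")),
            m3s_to_mlmin(base.mean_flow("LMCA")),
            m3s_to_mlmin(result.mean_collateral_flow("contralateral")),
            m3s_to_mlmin(base.mean_collateral_flow("contralateral")),
        )
        row["ipsilateral_flow_ratio"] = metrics.ipsilateral_ratio
        row["mca_compensation_pct"] = 100.0 * metrics.compensation_fraction
        row["contralateral_flow_ratio"] = metrics.contralateral_ratio

    row["converged"] = result.converged
    row["mass_error_max"] = result.mass_error_max
    return row


def sweep(scores, occluded: bool = True,
          base_scenario: ScenarioConfig | None = None) -> pd.DataFrame:
    """One summary row per collateral score at the given occlusion state.

    The Windkessel set is calibrated per anatomy on its own baseline; for
    occluded sweeps the baseline run of the same anatomy supplies the
    recruitment-ratio denominators.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("need at least one collateral score")
    rows = []
    for score in scores:
        scenario = ScenarioConfig(
            score=score, occluded=occluded,
            network_config=(base_scenario.network_config
                            if base_scenario else None),
            waveform_csv=(base_scenario.waveform_csv
                          if base_scenario else None),
            seed=base_scenario.seed if base_scenario else 0,
            max_iter=base_scenario.max_iter if base_scenario else 25,
        )
        rows.append(_scenario_row(run_scenario(scenario)))
    return pd.DataFrame(rows)


def timeseries_frame(result: SimulationResult) -> pd.DataFrame:
    """Long-format time series: time_s, boundary, pressure_mmHg,
    flow_mL_min (clot probes and collateral channels included)."""
    frames = []
    for name in (*result.inlet_names, *result.outlet_names):
        frames.append(pd.DataFrame({
            "time_s": result.time,
            "boundary": name,
            "pressure_mmHg": result.pressures[name] / 133.322,
            "flow_mL_min": result.flows[name] * 6e7,
        }))
    for side, series in result.collateral_flows.items():
        frames.append(pd.DataFrame({
            "time_s": result.time,
            "boundary": f"collateral_{side}",
            "pressure_mmHg": np.nan,
            "flow_mL_min": series * 6e7,
        }))
    for face, series in result.clot_pressures.items():
        frames.append(pd.DataFrame({
            "time_s": result.time,
            "boundary": f"clot_{face}",
            "pressure_mmHg": series / 133.322,
            "flow_mL_min": np.nan,
        }))
    return pd.concat(frames, ignore_index=True)


def write_timeseries_csv(result: SimulationResult, path: str | Path) -> None:
    timeseries_frame(result).to_csv(path, index=False, float_format="%.10g")
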