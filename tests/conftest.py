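"""Shared fixtures: one calibration and a handful of simulations reused
across the whole suite (session scope keeps the full run fast)."""

import copy

import pytest

from willisflow.calibration import CalibrationTargets, calibrate
from willisflow.network import CollateralScore, build_network, default_network_config
from willisflow.scenario import make_inlet_waveforms, simulation_config_from
from willisflow.simulator import default_windkessels, run


@pytest.fixture(scope="session")
def network_config():
    return default_network_config()


@pytest.fixture(scope="session")
def sim_config(network_config):
    return simulation_config_from(network_config)


@pytest.fixture(scope="session")
def inlet_waveforms(network_config, sim_config):
    return make_inlet_waveforms(network_config, sim_config.period, seed=0,
                                dt=sim_config.dt)


@pytest.fixture(scope="session")
def calibration_cs0(network_config, sim_config, inlet_waveforms):
    """Windkessel set calibrated on the CS0 baseline network."""
    network = build_network(CollateralScore.CS0, occluded=False,
                            config=network_config)
    return calibrate(network, CalibrationTargets.from_config(network_config),
                     inlet_waveforms, sim_config,
                     windkessels=default_windkessels(network_config))


@pytest.fixture(scope="session")
def baseline_cs0(calibration_cs0):
    """Calibrated CS0 baseline simulation result."""
    return calibration_cs0.result


@pytest.fixture(scope="session")
def occluded_cs0(network_config, sim_config, inlet_waveforms, calibration_cs0):
    """CS0 network with the M1-LMCA clot, calibrated Windkessels."""
    network = build_network(CollateralScore.CS0, occluded=True,
                            config=network_config)
    wk = copy.deepcopy(calibration_cs0.windkessels)
    return run(network, inlet_waveforms, sim_config, windkessels=wk)


@pytest.fixture(scope="session")
def occlusion_sweep(network_config, sim_config, inlet_waveforms):
    """(baseline, occluded) result pair per collateral score CS1..CS4,
    each anatomy calibrated on its own baseline."""
    pairs = {}
    for score in (CollateralScore.CS1, CollateralScore.CS2,
                  CollateralScore.CS3, CollateralScore.CS4):
        baseline = build_network(score, occluded=False, config=network_config)
        cal = calibrate(baseline,
                        CalibrationTargets.from_config(network_config),
                        inlet_waveforms, sim_config,
                        windkessels=default_windkessels(network_config))
        occluded = build_network(score, occluded=True, config=network_config)
        wk = copy.deepcopy(cal.windkessels)
        pairs[score] = (cal.result,
                        run(occluded, inlet_waveforms, sim_config,
                            windkessels=wk))
    return pairs
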