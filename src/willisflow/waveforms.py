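"""Pulsatile inlet flow waveforms.

The clinical inflow boundary conditions are phase-contrast MRI (PCMRI)
waveforms from the ICAs and the basilar artery.  The underlying MRI sample
points are not publicly tabulated, so this module synthesises PCMRI-like
waveforms: a single systolic peak in the first third of the cycle, a smooth
diastolic decay, strictly positive flow, cubic-spline smoothness, periodic
continuity, and an exactly prescribed mean.  The synthetic shape is the
package's stand-in for the unpublished MRI samples; only the mean flow,
period, and qualitative shape are matched to the study conditions
(LICA 243, RICA 235, BA 127 mL/min, 857 ms cycle at 70 beats/min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .units import MLMIN_PER_M3S

__all__ = [
    "FlowWaveform",
    "interpolate_waveform",
    "scale_to_mean",
    "tile_cycles",
    "synth_inlet_waveform",
    "DEFAULT_PERIOD",
    "DEFAULT_INLET_MEANS_MLMIN",
]

DEFAULT_PERIOD = 0.857  # s, 70 beats/min
DEFAULT_INLET_MEANS_MLMIN = {"LICA": 243.07, "RICA": 235.25, "BA": 127.05}

# Relative single-peak pulse shape (fraction of period, relative flow).
# Systolic upstroke peaks near 0.16 T; gentle dicrotic shoulder then a flat
# diastolic runoff.  The first and last values coincide (periodic).
_PULSE_SHAPE = (
    (0.00, 0.78), (0.06, 0.86), (0.12, 1.62), (0.16, 1.80), (0.22, 1.38),
    (0.30, 1.02), (0.40, 0.96), (0.50, 0.90), (0.62, 0.86), (0.75, 0.82),
    (0.88, 0.79), (1.00, 0.78),
)

# Mild per-vessel pulsatility adjustment: the basilar waveform is slightly
# less pulsatile than the carotid ones.
_PULSATILITY = {"LICA": 1.00, "RICA": 0.97, "BA": 0.80}


@dataclass(frozen=True)
class FlowWaveform:
    """One period of a periodic volumetric flow signal, SI units.

    ``times`` is strictly increasing over [0, period] with
    flows[0] == flows[-1] (periodic continuity); ``mean_flow`` is the
    trapezoidal time average over the period.
    """

    times: np.ndarray
    flows: np.ndarray
    period: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        flows = np.asarray(self.flows, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "flows", flows)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if flows.shape != times.shape:
            raise ValueError("times and flows must have matching shapes")

    @property
    def mean_flow(self) -> float:
        return float(np.trapezoid(self.flows, self.times)
                     / (self.times[-1] - self.times[0]))

    @property
    def pulsatility_index(self) -> float:
        """(max - min) / mean, invariant under linear scaling."""
        return float((self.flows.max() - self.flows.min()) / self.mean_flow)

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Periodic evaluation at arbitrary times (cubic, periodic ends)."""
        spline = CubicSpline(self.times, self.flows, bc_type="periodic")
        return spline(np.mod(np.asarray(t, dtype=float), self.period))


def interpolate_waveform(samples, dt: float,
                         bc_type: str = "periodic") -> FlowWaveform:
    """Cubic-spline interpolation of (time, flow) samples onto a dt grid.

    The interpolant passes through every sample exactly.  With the default
    periodic end conditions the sample list must close the cycle
    (first and last flow equal); the period is the sampled time span.
    """
    pts = np.asarray(list(samples), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (time, flow) samples")
    t, q = pts[:, 0], pts[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if bc_type == "periodic" and not np.isclose(q[0], q[-1], rtol=1e-9,
                                                atol=0.0):
        raise ValueError("periodic interpolation requires first flow == last")
    period = float(t[-1] - t[0])
    spline = CubicSpline(t, q, bc_type=bc_type)
    n = int(round(period / dt))
    grid = t[0] + np.linspace(0.0, period, n + 1)
    return FlowWaveform(times=grid - t[0], flows=spline(grid), period=period)


def scale_to_mean(waveform: FlowWaveform, target_mean: float) -> FlowWaveform:
    """Linearly rescale so the trapezoidal mean equals ``target_mean``.

    Pure amplitude scaling: the normalized shape (hence the pulsatility
    index) is unchanged.
    """
    current = waveform.mean_flow
    if current == 0.0:
        raise ValueError("cannot rescale a zero-mean waveform")
    factor = target_mean / current
    return FlowWaveform(times=waveform.times, flows=waveform.flows * factor,
                        period=waveform.period)


def tile_cycles(waveform: FlowWaveform, n_cycles: int):
    """Concatenate ``n_cycles`` identical cardiac cycles.

    Returns (times, flows) covering [0, n_cycles * period]; the shared
    cycle-boundary sample appears once.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    t0, q0 = waveform.times, waveform.flows
    times = [t0]
    flows = [q0]
    for k in range(1, n_cycles):
        times.append(t0[1:] + k * waveform.period)
        flows.append(q0[1:])
    return np.concatenate(times), np.concatenate(flows)


def synth_inlet_waveform(vessel: str,
                         mean_flow: float | None = None,
                         period: float = DEFAULT_PERIOD,
                         shape_params=None,
                         seed: int = 0,
                         jitter: float = 0.0,
                         dt: float = 1e-3) -> FlowWaveform:
    """Synthetic PCMRI-like inlet waveform with an exact mean, SI units.

    ``mean_flow`` is in m^3/s (defaults to the study mean for the vessel);
    ``shape_params`` optionally overrides the (t/T, relative flow) control
    points.  ``jitter`` adds seeded multiplicative noise to the control
    points before splining (default off); for fixed arguments the output is
    bit-reproducible.
    """
    if vessel not in DEFAULT_INLET_MEANS_MLMIN:
        raise ValueError(f"unknown inlet vessel {vessel!r}")
    if mean_flow is None:
        mean_flow = DEFAULT_INLET_MEANS_MLMIN[vessel] / MLMIN_PER_M3S
    if mean_flow <= 0:
        raise ValueError("mean_flow must be positive")
    if period <= 0:
        raise ValueError("period must be positive")

    shape = np.asarray(shape_params if shape_params is not None
                       else _PULSE_SHAPE, dtype=float)
    frac, rel = shape[:, 0].copy(), shape[:, 1].copy()
    # flatten the pulse toward its mean for less pulsatile vessels
    pulsatility = _PULSATILITY.get(vessel, 1.0)
    rel = rel.mean() + pulsatility * (rel - rel.mean())
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        noise = 1.0 + jitter * rng.standard_normal(rel.size - 1)
        rel[1:-1] *= noise[1:]
        rel[0] = rel[-1] = rel[0] * noise[0]
    if np.any(rel <= 0):
        raise ValueError("pulse shape must stay strictly positive")

    wave = interpolate_waveform(np.column_stack([frac * period, rel]), dt=dt)
    if wave.flows.min() <= 0:
        raise ValueError("interpolated pulse shape dipped below zero")
    return scale_to_mean(wave, mean_flow)
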