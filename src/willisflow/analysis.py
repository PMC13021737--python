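"""Hemodynamic summary statistics and clot/catheter force calculations.

Summary conventions: MAP = (2*P_dia + P_sys)/3; mean flow is the
trapezoidal time average over an integer number of cardiac cycles;
systemic systolic/diastolic pressures are the averages of the per-inlet
maxima/minima over the three proximal inlet vessels.

Clot compaction forces: the occlusive plug is treated as static, loaded by
the proximal and distal pressures acting on the respective clot faces,

    F_mean = MAP_prox * A_prox - MAP_dist * A_dist
    F_max  = P_sys,prox * A_prox - P_sys,dist * A_dist

and the static aspiration-catheter tip force is F_cath = P_v * pi/4 * D^2,
whose inverse gives the minimum catheter lumen diameter able to overcome a
given compaction force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import PA_PER_MMHG

__all__ = [
    "map_calc",
    "mean_flow",
    "systemic_pressures",
    "CompactionForceInputs",
    "compaction_forces",
    "CatheterSpec",
    "catheter_tip_force",
    "min_catheter_diameter",
    "collateral_metrics",
    "CollateralMetrics",
    "cbf_summary",
    "HemodynamicSummary",
]


def map_calc(p_dia: float, p_sys: float) -> float:
    """Mean arterial pressure (2*P_dia + P_sys)/3; unit-agnostic."""
    if p_dia > p_sys:
        raise ValueError("diastolic pressure exceeds systolic pressure")
    return (2.0 * p_dia + p_sys) / 3.0


def mean_flow(times: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal time average (1/T) * integral of the series.

    The window should cover an integer number of cardiac cycles (the caller
    enforces cycle alignment); works identically for flow or pressure.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("series must cover at least one cycle")
    span = times[-1] - times[0]
    if span <= 0:
        raise ValueError("times must be increasing")
    return float(np.trapezoid(values, times) / span)


def systemic_pressures(inlet_traces) -> tuple:
    """(sSBP, sDBP, systemic MAP) from the proximal inlet pressure traces.

    sSBP/sDBP are the arithmetic means of the per-inlet maxima/minima.
    """
    traces = [np.asarray(t, dtype=float) for t in inlet_traces]
    if not traces:
        raise ValueError("need at least one inlet trace")
    ssbp = float(np.mean([t.max() for t in traces]))
    sdbp = float(np.mean([t.min() for t in traces]))
    return ssbp, sdbp, map_calc(sdbp, ssbp)


@dataclass(frozen=True)
class HemodynamicSummary:
    """Systemic pressure summary in mmHg."""

    systolic_mmhg: float
    diastolic_mmhg: float

    @property
    def map_mmhg(self) -> float:
        return map_calc(self.diastolic_mmhg, self.systolic_mmhg)

    @property
    def pulse_pressure_mmhg(self) -> float:
        return self.systolic_mmhg - self.diastolic_mmhg


@dataclass(frozen=True)
class CompactionForceInputs:
    """Clot-face pressures (mmHg) and face areas (m^2).

    Default areas are the proximal/distal clot-face cross sections of the
    M1 plug (7.40 and 6.38 mm^2).  Systolic pressures are optional: without
    them only the mean force is defined.
    """

    map_proximal_mmhg: float
    map_distal_mmhg: float
    sys_proximal_mmhg: float | None = None
    sys_distal_mmhg: float | None = None
    area_proximal: float = 7.40e-6
    area_distal: float = 6.38e-6

    def __post_init__(self) -> None:
        if self.area_proximal <= 0 or self.area_distal <= 0:
            raise ValueError("clot face areas must be positive")


def compaction_forces(inputs: CompactionForceInputs) -> tuple:
    """(F_mean, F_max) in newtons; F_max is None when systolic pressures
    are not supplied (it is never estimated from MAPs)."""
    f_mean = (inputs.map_proximal_mmhg * PA_PER_MMHG * inputs.area_proximal
              - inputs.map_distal_mmhg * PA_PER_MMHG * inputs.area_distal)
    if inputs.sys_proximal_mmhg is None or inputs.sys_distal_mmhg is None:
        return f_mean, None
    f_max = (inputs.sys_proximal_mmhg * PA_PER_MMHG * inputs.area_proximal
             - inputs.sys_distal_mmhg * PA_PER_MMHG * inputs.area_distal)
    return f_mean, f_max


@dataclass(frozen=True)
class CatheterSpec:
    """Aspiration catheter: vacuum pressure P_v (Pa) and internal lumen
    diameter (m)."""

    vacuum_pressure: float
    internal_diameter: float

    def __post_init__(self) -> None:
        if self.vacuum_pressure <= 0 or self.internal_diameter <= 0:
            raise ValueError("vacuum pressure and diameter must be positive")


def catheter_tip_force(spec: CatheterSpec) -> float:
    """Static tip force P_v * (pi/4) * D^2 in newtons."""
    return spec.vacuum_pressure * math.pi / 4.0 * spec.internal_diameter ** 2


def min_catheter_diameter(required_force: float,
                          vacuum_pressure: float) -> float:
    """Smallest internal lumen diameter whose tip force at ``vacuum_pressure``
    reaches ``required_force``; exact inverse of catheter_tip_force."""
    if required_force <= 0 or vacuum_pressure <= 0:
        raise ValueError("force and vacuum pressure must be positive")
    return math.sqrt(4.0 * required_force / (math.pi * vacuum_pressure))


@dataclass(frozen=True)
class CollateralMetrics:
    """Collateral recruitment summary.

    ``ipsilateral_ratio`` is occluded/baseline mean ipsilateral collateral
    flow; ``compensation_fraction`` is the occluded ipsilateral collateral
    flow over the same anatomy's baseline LMCA mean flow (how much of the
    lost MCA flow the collateral replaces); ``contralateral_ratio`` is
    occluded/baseline on the contralateral side (None when that channel is
    not supplied).
    """

    ipsilateral_ratio: float
    compensation_fraction: float
    contralateral_ratio: float | None = None


def collateral_metrics(occluded_ipsi_flow: float,
                       baseline_ipsi_flow: float,
                       baseline_lmca_flow: float,
                       occluded_contra_flow: float | None = None,
                       baseline_contra_flow: float | None = None
                       ) -> CollateralMetrics:
    """Recruitment metrics from mean collateral flows (any common unit).

    Flows enter as magnitudes: baseline collateral flow may be oriented
    either way (antegrade, low-gradient) while the occluded flow is
    retrograde ACA -> MCA, so signed ratios would be meaningless.  With no
    collateral element (CS0) the baseline flow is zero and the ratio is
    undefined.
    """
    if baseline_ipsi_flow == 0.0:
        raise ValueError("collateral metrics undefined without a collateral "
                         "element (zero baseline collateral flow)")
    if baseline_lmca_flow <= 0.0:
        raise ValueError("baseline LMCA mean flow must be positive")
    ratio = abs(occluded_ipsi_flow) / abs(baseline_ipsi_flow)
    compensation = abs(occluded_ipsi_flow) / baseline_lmca_flow
    contra = None
    if occluded_contra_flow is not None and baseline_contra_flow not in (None, 0.0):
        contra = abs(occluded_contra_flow) / abs(baseline_contra_flow)
    return CollateralMetrics(ipsilateral_ratio=ratio,
                             compensation_fraction=compensation,
                             contralateral_ratio=contra)


def cbf_summary(inlet_means_ml_min: dict) -> dict:
    """Total cerebral blood flow and its anterior/posterior split.

    ``inlet_means_ml_min`` maps LICA/RICA/BA to mean inflows; the anterior
    fraction is the carotid (LICA+RICA) share of the total.
    """
    total = float(sum(inlet_means_ml_min.values()))
    anterior = float(inlet_means_ml_min.get("LICA", 0.0)
                     + inlet_means_ml_min.get("RICA", 0.0))
    return {
        "total_cbf_ml_min": total,
        "anterior_fraction": anterior / total,
        "posterior_fraction": 1.0 - anterior / total,
    }
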