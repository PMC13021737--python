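"""Unit conversion constants.

All internal computation is in SI (Pa, m, s, m^3/s).  Clinical units
(mmHg, mL/min) appear only at I/O boundaries.
"""

PA_PER_MMHG: float = 133.322
"""Pascal per millimetre of mercury."""

MLMIN_PER_M3S: float = 6.0e7
"""mL/min per m^3/s."""


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * PA_PER_MMHG


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / PA_PER_MMHG


def mlmin_to_m3s(q_mlmin: float) -> float:
    return q_mlmin / MLMIN_PER_M3S


def m3s_to_mlmin(q_m3s: float) -> float:
    return q_m3s * MLMIN_PER_M3S
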