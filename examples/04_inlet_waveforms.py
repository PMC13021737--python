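"""Synthetic PCMRI-like inlet waveforms: construction and manipulation.

Shows the waveform toolbox: synthesis with an exact mean, rescaling to a
patient-specific mean flow, tiling over the 6 s / 7-cycle protocol, and
round-tripping through a CSV of (time, flow) samples.
"""

import numpy as np
import pandas as pd

from willisflow import interpolate_waveform, scale_to_mean, synth_inlet_waveform, tile_cycles
from willisflow.units import m3s_to_mlmin, mlmin_to_m3s

wave = synth_inlet_waveform("LICA")
print(f"LICA waveform: mean {m3s_to_mlmin(wave.mean_flow):.2f} mL/min, "
      f"period {wave.period * 1e3:.0f} ms, "
      f"pulsatility index {wave.pulsatility_index:.2f}, "
      f"min flow {m3s_to_mlmin(wave.flows.min()):.1f} mL/min (always > 0)")

patient = scale_to_mean(wave, mlmin_to_m3s(310.0))
print(f"rescaled to a high-flow patient: mean "
      f"{m3s_to_mlmin(patient.mean_flow):.1f} mL/min, "
      f"pulsatility index unchanged at {patient.pulsatility_index:.2f}")

t, q = tile_cycles(wave, 7)
print(f"tiled 7 cycles: {t[-1]:.3f} s of signal "
      f"(the 6 s simulation protocol), "
      f"tiled mean {m3s_to_mlmin(np.trapezoid(q, t) / t[-1]):.2f} mL/min")

# CSV round trip: write coarse samples, re-interpolate with the periodic
# cubic spline the simulator uses
coarse = np.append(wave.times[::40], wave.times[-1])  # close the cycle
samples = pd.DataFrame({"time_s": coarse,
                        "LICA_ml_min": m3s_to_mlmin(wave.sample(coarse))})
back = interpolate_waveform(
    np.column_stack([samples["time_s"],
                     mlmin_to_m3s(samples["LICA_ml_min"].to_numpy())]),
    dt=1e-3)
print(f"CSV round trip through {len(samples)} samples: mean "
      f"{m3s_to_mlmin(back.mean_flow):.2f} mL/min")
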