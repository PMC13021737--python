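"""Pre/post-occlusion comparison across collateral development levels.

For each collateral score CS0..CS4, calibrates the anatomy's baseline,
inserts the 5 mm porous clot in the proximal M1-LMCA, and tabulates the
quantities that drive stroke-therapy success: residual LMCA flow,
retrograde collateral recruitment, the pressure drop across the clot, and
the resulting compaction forces.
"""

from willisflow import CollateralScore
from willisflow.scenario import ScenarioConfig, run_scenario, _scenario_row
import pandas as pd

rows = []
for score in CollateralScore:
    outcome = run_scenario(ScenarioConfig(score=score, occluded=True))
    rows.append(_scenario_row(outcome))

table = pd.DataFrame(rows)
cols = ["score", "systemic_map_mmhg", "flow_LMCA_ml_min",
        "clot_map_proximal_mmhg", "clot_map_distal_mmhg",
        "clot_delta_p_map_mmhg", "f_mean_mn", "f_max_mn"]
print(table[cols].round(2).to_string(index=False))

print()
coll_cols = ["score", "collateral_ipsilateral_ml_min",
             "ipsilateral_flow_ratio", "mca_compensation_pct",
             "contralateral_flow_ratio"]
print(table[[c for c in coll_cols if c in table.columns]]
      .round(2).to_string(index=False))

print("\nInterpretation: larger collaterals restore distal MCA perfusion "
      "(higher LMCA flow and compensation %), raise the distal clot-face "
      "pressure, and so unload the clot (lower delta-P and compaction "
      "forces) - the haemodynamic basis for better thrombectomy and "
      "thrombolysis odds in well-collateralised patients.")
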