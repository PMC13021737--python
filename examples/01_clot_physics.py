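"""Clot microstructure -> permeability -> hydraulic resistance -> forces.

Builds the reference fibrin clot (250 nm fibre radius, 18% fibrin volume
fraction, 5 mm plug) and walks through the closed-form physics: Davies
permeability, lumped Darcy resistance, compaction forces on the clot faces,
and the aspiration-catheter lumen needed to overcome them.
"""

from willisflow import (
    CatheterSpec,
    ClotModel,
    CompactionForceInputs,
    catheter_tip_force,
    compaction_forces,
    min_catheter_diameter,
)

clot = ClotModel()  # defaults: R_f = 250 nm, Phi_f = 0.18, L = 5 mm
mu = 4e-3  # Pa.s, blood dynamic viscosity

print(f"permeability        : {clot.permeability * 1e12:.4f} um^2")
print(f"porosity            : {clot.porosity:.2f}")
print(f"Darcy resistance    : {clot.darcy_resistance(mu):.3g} Pa.s/m^3")

# Compaction forces from clot-face mean arterial pressures (mmHg): the
# no-collateral extreme (proximal 117.8, distal ~0) versus the well-
# collateralised extreme (99.2 / 58.8).
for label, p_prox, p_dist in [("no collaterals  ", 117.8, 0.0),
                              ("large collaterals", 99.2, 58.8)]:
    f_mean, _ = compaction_forces(CompactionForceInputs(p_prox, p_dist))
    print(f"F_mean {label}: {f_mean * 1e3:6.1f} mN")

# An aspiration catheter must beat the distal compaction force: at a pump
# vacuum of 91.6 kPa, the minimum lumen for the worst case (172.7 mN peak).
p_vac = 91.6e3  # Pa
d_min = min_catheter_diameter(0.1727, p_vac)
print(f"minimum catheter lumen at {p_vac / 1e3:.1f} kPa vacuum: "
      f"{d_min * 1e3:.3f} mm ({d_min / 25.4e-3:.3f} in)")
print(f"  check: tip force at that lumen = "
      f"{catheter_tip_force(CatheterSpec(p_vac, d_min)) * 1e3:.1f} mN")
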