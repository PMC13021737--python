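# Methods

## Model structure and assumptions

The package is a 0D (lumped-parameter) surrogate of pulsatile blood flow
through a complete Circle of Willis.  Blood is incompressible and
Newtonian (density 1060 kg/m³, kinematic viscosity 3.77×10⁻⁶ m²/s; the
dynamic viscosity is their product, ≈ 4×10⁻³ Pa·s).  Every vessel is a
resistor: Hagen–Poiseuille for patent segments, a Darcy plug for the
clot.  Segments carry no inertance and no distributed compliance — all
dynamics live in the outlet Windkessel compliances.  Consequences:

- Mean flows and mean/formula arterial pressures are the trustworthy
  outputs; they are set by the resistive network and the RCR outlets.
- Pulse-pressure fine structure (waveform shape, wave reflection,
  systolic augmentation) is approximate.  The calibrated model reproduces
  a physiologic pulse (≈ 123/74 mmHg at the inlets) but a somewhat
  smaller pulse pressure than the 130.5/70.4 mmHg clinical operating
  point, because a compliance-only outlet cannot reshape the pressure
  waveform independently of the prescribed flow waveform.
- Inlets prescribe flow.  Total cerebral blood flow (605.4 mL/min;
  79% anterior) is therefore conserved after occlusion, so systemic
  pressures rise to push the same flow through fewer beds — the model's
  (deliberate) analogue of the acute hypertensive response, shared with
  the 3D model it emulates.

The network graph: LICA/RICA terminate at the carotid termini feeding
M1-MCA and A1-ACA; the basilar terminus feeds P1-PCA and the two SCAs;
AComA joins the ACA junctions, PComAs join each carotid terminus to the
ipsilateral PCA junction.  The M1-LMCA is always built as
proximal (2 mm) / mid (5 mm) / distal (13 mm) sub-segments; occlusion
replaces the mid sub-segment's Poiseuille resistance with the clot's
Darcy resistance, so the two flanking nodes double as the proximal/distal
clot-face pressure probes, and removing the clot recovers the baseline
network exactly.

Major-vessel lengths and diameters are literature-typical values for an
adult CoW (e.g. ICA 4.5 mm, M1 3.0 mm, A1 2.3 mm, P1 2.1 mm diameter;
SCA 1.48 mm).  They are not patient-derived: segment resistances are one
to two orders of magnitude below the outlet resistances, so the Windkessel
calibration absorbs residual geometric mismatch, and the validation
surface is flows and pressures, not geometry.

## Clot element

The clot is a fibrous (fibrin) porous plug: fibre radius R_f = 250 nm,
fibrin volume fraction Φ_f = 0.18 (porosity Φ = 0.82), length 5 mm.
Davies' correlation gives k = R_f²/(16 Φ_f^1.5 (1+56 Φ_f³)) = 0.0386 µm².
The lumped resistance uses Darcy's law in superficial-velocity form,
R = µL/(kA) = 7.5×10¹³ Pa·s/m³, with A the mean of the proximal/distal
clot-face areas (7.40, 6.38 mm²).  The Φ² interstitial-velocity factor
that appears in the momentum form of the porous drag is absorbed by the
superficial-flux identity q = Φ·u_f; a 0D element must relate volumetric
flow to pressure drop, and the superficial convention is the standard
lumped form.

Known limitation: a 3D finite-volume clot has a somewhat higher effective
resistance than µL/(kA) (Brinkman wall shear, entrance/exit effects, and
the non-uniform velocity profile across the faces).  With the occluded
proximal pressure at its physiologic ~118–120 mmHg, the lumped element
passes ≈ 0.013 mL/min through the occluded LMCA where the 3D reference
reports < 0.01 mL/min — the same "near-total arrest" physiology
(a > 99.99% flow reduction), but the absolute residual trickle is ~30%
higher in 0D.  We keep the standard Darcy form rather than introducing an
ad hoc correction factor.

## Collateral element

Each hemisphere's leptomeningeal network is one resistor from the distal
ACA node to the distal MCA node, oriented ACA→MCA so retrograde
recruitment after occlusion is a positive flow.  Scores: CS0 absent
(element omitted entirely — not a large finite resistance, which would
add conditioning noise), CS1–CS4 with lengths 35.5/35.5/34.8/34.8 mm and
diameters 0.75/1.00/1.25/1.50 mm (resistances 18.3 → 1.1 ×10⁹ Pa·s/m³).
Because the 0D collateral connects outlet node to outlet node, its
driving pressure difference is somewhat larger than between the 3D
mid-collateral baffles; recruitment flows are therefore higher than the
3D reference in absolute terms (e.g. ~37 vs ~20 mL/min for CS1) while
preserving the monotone ordering and the qualitative plateau at large
calibres.  Recruitment metrics (occluded/baseline ratio, MCA
compensation fraction) use flow magnitudes, since the baseline
low-gradient collateral flow can be oriented either way.

## Inlet waveforms (synthetic data)

The clinical boundary conditions are PCMRI-derived pulsatile waveforms
whose sample points are not publicly tabulated.  The generator therefore
emulates them: a fixed table of (t/T, relative flow) control points with a
single systolic peak at 0.16 T, a dicrotic shoulder, and a flat diastolic
runoff, interpolated with a periodic cubic spline at 1 ms and rescaled to
the exact prescribed mean (LICA 243.07, RICA 235.25, BA 127.05 mL/min —
the realized inlet means of the reference model, so total CBF and its
79/21 anterior/posterior split are reproduced by construction).  The BA
pulse is flattened to 80% relative amplitude (posterior waveforms are
less pulsatile).  Period 857 ms (70 beats/min).  Waveforms are strictly
positive, C²-continuous across the cycle boundary, and bit-reproducible;
a seeded jitter on the control points exists for robustness studies and
is off by default.  What passing tests show: the simulator's response to
a physiologic single-peak pulse with exact clinical means.  What they do
not show: sensitivity to true patient waveform shapes (notch timing,
beat-to-beat variability), which the synthetic shape does not carry.

Spline end conditions are periodic by default (cycle repetition requires
C¹ continuity at the seam); `interpolate_waveform` exposes `bc_type` for
non-periodic uses, and the classical "exact on cubics" property holds
under `not-a-knot` ends.

## Numerical scheme

Per time step (default dt = 1 ms, duration 6 s = 7 cycles):

1. solve the resistive network with Kirchhoff's current law — prescribed
   inlet flows injected as current sources, each outlet coupled through
   1/R₁ to its (known) compliance-state pressure.  The conductance matrix
   is constant, so it is LU-factorised once per run; each step is a
   back-substitution.  Systems with condition number above 10¹² are
   rejected as topologically singular (an exactly singular block with a
   zero right-hand side can otherwise slip through the dense solver).
2. advance each Windkessel state with the exact integrating-factor update
   P_c ← P_ref + QR₂ + (P_c − P_ref − QR₂)e^(−dt/(R₂C)), holding Q at the
   step's left endpoint (local error O(dt²), unconditionally stable for
   stiff R₂C).

States initialise at the steady operating point of the mean inflow
(P_c = P_ref + Q̄R₂ from a steady presolve), which makes the transient
comfortably shorter than the two discarded cycles; convergence to a
periodic state is verified after the fact (cycle-to-cycle MAP drift
< 0.5% in every boundary) and flagged as a warning, never silently.
Mass conservation (inlet sum vs outlet sum) holds to solver precision
(~10⁻¹⁴ relative) and is checked at every step against a 10⁻⁸ bound.

Analysis windows always span whole cardiac cycles: with the defaults,
cycles 3–7 (t ∈ [1.714, 5.999] s).  MAP uses the (2·dia + sys)/3 formula
over the window; the clot pressure drop is reported in both conventions —
difference of face MAPs and time-averaged instantaneous drop — because
the two differ by up to ~1 mmHg and published tables mix them.

## Windkessel calibration

Targets: the eight clinical mean outlet flows (LACA 79, LMCA 146, LPCA
61, RACA 86, RMCA 133, RPCA 58 mL/min; SCAs have no clinical measurement
and target the model-derived 28.1 mL/min) plus systemic 130.5/70.4 mmHg,
all at 10% relative tolerance.  Starting parameters are the published
calibrated RCR values for the six ACA/MCA/PCA outlets; SCA starting
values are PCA parameters scaled by the target-flow ratio.

Each iteration runs the full pulsatile simulation and applies three
damped multiplicative corrections (exponent 0.8, which kills the
fixed-point oscillation the undamped update exhibits):

1. per-outlet R₁,R₂ × (Q_sim/Q_target)^0.8 — sets the flow split and
   preserves each outlet's R₁:R₂ ratio;
2. all resistances × (MAP_target/MAP_sim)^0.8 — with prescribed inflow
   the split correction cannot fix the absolute pressure level (scaling
   every resistance together changes no flow), so the level is pinned to
   the systemic MAP implied by the pressure targets;
3. all compliances × (PP_sim/PP_target)^0.8 — pulse-pressure matching,
   skipped when either pulse pressure is degenerate (constant-flow
   circuits).

Resistance and compliance adjustments are interleaved within one
iteration (resistances first); the scheme converges on the shipped
defaults in 3 iterations with every flow within 3.1% and pressures within
6%.  Convergence declares only when *all* targets are inside tolerance;
hitting max_iter (default 25) raises with the per-target residuals.  On
its own output the loop terminates after a single verification run with
parameters untouched.

## Scale of the shipped experiments

All defaults are desk-scale: one simulation is 6000 steps of a ~22-node
dense solve (~0.1 s), a calibration is 3–5 simulations, and the full
five-anatomy occlusion sweep with per-anatomy calibration runs in a few
seconds on one CPU.  These sizes are the package's standard protocol, and
the acceptance script uses exactly them.

## Known limitations

- No vessel compliance/inertance, no wave propagation: pulse-pressure
  detail and waveform morphology are approximate (see above).
- Constant inlet flow distribution post-occlusion: no carotid flow
  redistribution or autoregulatory adaptation; the collateral resistance
  is static (no vasodilation dynamics).
- The lumped clot underestimates the 3D effective clot resistance by
  ~25–35%, so the residual occluded-LMCA trickle is overestimated in the
  same proportion (0.013 vs < 0.01 mL/min) although both are functionally
  zero against a 143 mL/min baseline.
- The 0D collateral overestimates absolute recruitment flows relative to
  the 3D reference while preserving orderings and trends; conclusions
  should rest on comparisons across scores, not absolute collateral
  mL/min.
- Complete-CoW anatomy only; fetal/hypoplastic variants are expressible
  through custom network YAML but unvalidated.
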