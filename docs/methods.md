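# Methods

## Physical model

The simulator treats a hot-liquid spill onto clothing as a one-dimensional,
multilayer transient conduction problem.  The domain is the soaked fabric
(−L ≤ x < 0) plus four tissue slabs (epidermis, dermis, subcutaneous fat,
muscle; 42 mm total), with the skin surface at x = 0.  One dimension is
adequate because the heat penetration depth over tens of seconds
(2√(a·t) ≈ 2–3 mm) is far smaller than the curvature radius of a thigh, and
far smaller than the 42 mm domain, so the adiabatic inner boundary never
influences the surface layers.

All thermal properties are constant: the temperature excursion is moderate
(≤ 86 °C) and the conductivity/heat-capacity variation of tissue and water
over that range is smaller than the biological uncertainty in the layer
properties themselves.

### Wet-fabric initial state

Spill wetting is modeled as instantaneous: at t = 0 the fabric pores fill
with liquid and the fabric-liquid composite equilibrates at the
energy-conserving mixing temperature

T0_wf = (ρ_f C_f T_f + ρ_w C_w T_w) / (ρ_f C_f + ρ_w C_w),

a volumetric-heat-capacity-weighted mean.  The pore-water concentration is
ρ_w = 800 kg/m³, chosen so that dry cotton (200 kg/m³) plus pore water sums
to the soaked-fabric density of 1000 kg/m³; with C_w = 4184 J/(kg·K) an
85 °C spill on 30 °C cotton yields 80.9 °C and a 90 °C spill yields 85.6 °C.
The soaked fabric conducts like water (k = 0.65 W/m·K at ~330 K) and stores
heat with the tabulated volumetric capacity ρC = 3.6×10⁶ J/(m³·K).  The
solver only ever needs the product ρC, so the printed volumetric value is
used directly (the separately printed soaked specific heat, 3470 J/kg·K at
1000 kg/m³, would imply a slightly smaller product; the difference shifts
the base-case damage integral by a few percent).

Thicker fabric in a scenario means proportionally more trapped hot water —
the mixing temperature is thickness-independent but the stored enthalpy is
not, which is why a 10 % thicker fabric produces a markedly larger damage
integral.

### Exposure stages

1. **Fabric contact** (0 < t ≤ t_off): conduction through fabric and skin in
   perfect thermal contact; the outer fabric face loses heat to ambient air
   through h_air.
2. **Fabric removed** (t_off < t ≤ t_cool): the fabric nodes are deleted
   together with their enthalpy — the clothing physically leaves, no energy
   bookkeeping crosses the event — and the skin surface convects to air.
3. **Water cooling** (t > t_cool): the surface film coefficient jumps to
   h_water with the running-water temperature as reservoir.

Water cooling through the clothing is not modeled; cooling therefore
requires prior fabric removal and the configuration layer rejects
`t_cool` without `t_off`.

### Blood perfusion and metabolism

The Pennes sink/source terms W_b ρ_b C_b (T_b − T) + Q_met act in the
vascular layers (dermis, subcutaneous, muscle) and are absent in the
avascular epidermis and in the fabric.  Defaults: W_b = 1.25×10⁻³ s⁻¹,
ρ_b = 1060 kg/m³, C_b = 3770 J/(kg·K), T_b = 37 °C, Q_met = 420 W/m³ —
representative literature values for resting skin, individually
configurable and disableable.  For exposures of tens of seconds the problem
is conduction-dominated; enabling or disabling the whole blood model moves
the base-case damage integral by well under 10 % (asserted in the tests),
so the precise perfusion constants are not critical.

### Parameters at a glance

| parameter | default | units | note |
|---|---|---|---|
| Δx | 10 | μm | grid spacing; every layer thickness must be a multiple |
| Δt | 2×10⁻⁴ | s | keeps max Fo ≈ 0.36 (soaked fabric) < 0.5 |
| h_air | 10 | W/m²K | still-air natural convection |
| h_water | 600 | W/m²K | running tap water on skin |
| T_air, T_water | 20, 20 | °C | ambient and tempered coolant; results are insensitive (the damage window closes within seconds of cooling onset) |
| T_skin(0) | 37 | °C | uniform initial skin temperature at every depth — slightly conservative, avoids an arbitrary initial gradient |
| P, ΔE | 3.1×10⁹⁸, 6.28×10⁵ | 1/s, J/mol | hot-water damage kinetics; ΔE is often quoted as 6.28×10⁸ J/kmol — the J/mol value is the one consistent with P and with any damage occurring at scald temperatures at all |
| gate | 43.0 | °C | damage accumulates only at or above this basal temperature |
| Ω limits | 0.53 / 1.0 | — | superficial / superficial partial-thickness classification, half-open intervals |

## Numerical scheme

### Discretization

Explicit forward-Euler, central-space (FTCS) on a **vertex-centered** grid:
nodes every Δx with all material interfaces exactly on nodes.  Each segment
between adjacent nodes then lies in a single material and carries that
material's conductance k/Δx — there is no interface-averaging ambiguity of
any kind.  A node's heat capacity is the sum of its two half-segments, so
an interface node holds half a cell of each neighbor material and boundary
nodes hold half a cell.  The scheme conserves enthalpy exactly with
insulated ends (asserted to round-off in the tests).

This layout was chosen over a cell-centered finite-volume grid for two
reasons.  First, the quantities of interest live at interfaces: the damage
integral is evaluated at the epidermis–dermis interface and the contact
temperature at the fabric–skin interface, and the vertex-centered grid
carries a node exactly there instead of interpolating between cell centers
(the interpolated cell-centered basal temperature is biased warm by the
convex temperature profile, which the exponential damage kinetics amplify
to ~10–20 % in Ω).  Second, the initial condition is cleanly expressible:
skin at 37 °C at every depth x ≥ 0 including the surface node, fabric at
T0_wf strictly inside x < 0.

The convective boundary applies the film flux h·(T_env − T₀) to the
outermost node using that node's temperature as the surface temperature —
first-order, and accurate here because the surface node *is* the surface.
A Dirichlet variant (surface held at fixed temperature) exists for
verification against the half-space solution.

### Stability

The explicit scheme requires Fo = a·Δt/Δx² < 0.5 in every cell; per node
the criterion is Δt·(g_left + g_right)/(2·capacity) < 0.5, which reduces to
the classical form in uniform material.  The guard runs at construction,
before any stepping, and reports the per-layer maxima (muscle 0.24, soaked
fabric 0.36 at the defaults).  Event times are rounded to the nearest step;
at Δt = 0.2 ms this is far below any physical significance.

### Damage integration

The Arrhenius rate is evaluated in log space (exp(ln P − ΔE/RT)) because
the 10⁹⁸ prefactor overflows IEEE doubles; agreement with a 40-digit
arbitrary-precision evaluation is asserted to 10 significant digits across
37–100 °C.  Ω is accumulated by the trapezoidal rule over the basal probe
series sampled every 0.01 s (a rectangle rule is available for sensitivity
checks; on these smooth series the two agree to well under 1 %).  The rate
is zeroed below the 43.0 °C gate rather than integrated everywhere.  Burn
depth is the deepest point where Ω ≥ 1, found by accumulating Ω on every
node of the coarser field snapshots (every 0.05 s) and interpolating the
crossing.

### Problem sizes

A standard scenario is 150 000 time steps on a 4 306-node grid (~3 s on one
CPU).  The grid-convergence check runs the base case at Δx = 5 μm,
Δt = 5×10⁻⁵ s over a 6 s horizon — long enough to contain the basal peak
(~2 s) and the bulk of the damage accumulation — and requires the basal
peak to move < 0.5 °C and Ω < 5 %.  The monotonicity sweeps in the
acceptance tests use an 8 s horizon for the same reason: the orderings are
fixed within the first few seconds because damage effectively stops once
the basal layer drops below the gate.

## What the scenario table exercises

The thirteen built-in cases vary one factor at a time around the base case
(85 °C, 1.0 mm fabric, 50 μm epidermis, no removal): removal at 2.5/5 s
with and without water cooling, epidermis 40–80 μm, fabric 0.9/1.1 mm,
spill 80/90 °C.  They probe the model's central claims: spill temperature
dominates (Ω spans 0.23–4.3 over 80–90 °C), early fabric removal halves the
injury, and water cooling applied after removal adds little because the
basal layer has already dropped below the gate by the time cooling can act.

## Limitations

- The spill is instantaneous and exactly saturates the fabric; continued
  pouring or excess liquid (which prolongs the heat supply and deepens the
  burn) is out of scope, so computed damage integrals are minimum estimates.
- No moisture transport, evaporation or radiative loss; no cooling through
  the clothing.
- Constant thermal properties; no temperature-dependent perfusion response
  (vasodilation needs ~20 s and the critical window is shorter).
- 1D geometry: valid for body sites whose curvature is large against the
  few-millimetre heat penetration depth.
- The ambient and cooling-water temperatures are weakly constrained by the
  underlying scenario definitions; the defaults (20 °C) matter little
  because damage accumulation has essentially ceased wherever they enter.
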