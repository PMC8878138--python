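# Methods

## Model overview

The package simulates density adaptation of a long-bone diaphysis under
axial compression. Three coupled ingredients:

1. **Geometry and material.** The diaphysis is an idealized solid cylinder,
   10 mm long, 1.5 mm outer radius. The dimensionless bone density at
   radius R (metres) is

       ρ(R) = atan(12000·(R − 0.0005)) / 3.4 + 0.56,

   an arctangent sigmoid with its inflection (ρ = 0.56) at the
   cortical-trabecular interface R = 0.5 mm, ρ ≈ 0.147 on the axis and
   ρ ≈ 0.998 at the outer surface. As written, the formula's
   parenthesization is ambiguous; this reading is the only one that keeps
   ρ ∈ (0, 1) over the section and the 0.56 inflection at 0.5 mm, and it
   matches the plotted distribution. Stiffness follows E = E₀·ρ² with
   E₀ = 20.3 GPa, ν = 0.3. The mass-density scale ρ_ref = 1 mg/mm³
   (1 g/cm³) converts dimensionless density to mass density.

2. **Mechanics.** Half-length axisymmetric model (symmetry plane at
   mid-height), structured bilinear quadrilateral mesh, default element
   size 0.1 mm, 2×2 Gauss quadrature, strain-energy density (SED)
   evaluated at element centroids. The axial force F = m·g (350 g body
   mass, scaled per scenario) is applied through a rigid frictionless
   platen: all top-face nodes share one axial displacement carrying F,
   the axis is radially fixed. Because E varies with radius only, this
   load case has an exact uniform-axial-strain solution with zero radial
   and hoop stress, which the bilinear elements represent exactly; the
   `iso_strain_reference` closed form (ε = F/∫E(r)·2πr dr,
   SED = ½E(r)ε²) therefore serves as an independent oracle and agrees
   with the FE path to well below 0.1% (the residual is the centroid
   sampling of E(r) across the interface). A density floor of 0.01 is
   applied when forming element stiffness so the near-empty medullary axis
   never makes the system singular. Energies are reported for the full
   bone (twice the modeled half). Units are mm/N/MPa, so energies come out
   in mJ and SED in mJ/mm³.

3. **Remodeling.** Cell activities are piecewise-linear in the elastic
   energy W, measured as deviations from the homeostatic level W₀
   (at W₀ both vanish — no remodeling at homeostasis):

   | quantity | value | units |
   |---|---|---|
   | W₀, W₁, W₂, W₃ | 3.1847, 3.7, 3.72, 3.78 | 10⁻⁴ mJ |
   | k₁, k₂ | +386.64×10⁵, −375×10⁵ | mg·mJ⁻¹·mm⁻³·(56 d)⁻¹ |
   | A₁, A₂ | +1992.36, −2232.38 | mg·mm⁻³·(56 d)⁻¹ |

   The caps satisfy A₁ = k₁(W₁−W₀) and A₂ = k₂(W₃−W₀) to printed
   precision; at exactly W = W₁ (W₃) the capped value applies. The
   osteoclast slope is stored negative so that resorption is negative
   throughout. The literal activity formula adds the baseline density to
   a rate, which is dimensionally inconsistent; the deviation-from-baseline
   form used here is the only reading consistent with the printed
   parameter identities and with zero remodeling at homeostasis.

   Each activity is modulated by (α − ρ)ⁿ — maximal in sparse bone where
   remodeling cells are abundant, vanishing as ρ → α ≈ 1 in dense cortex:
   α_ob = 1.0009, α_oc = 1.0 at W₁; α_ob = 1.0007, α_oc = 1.0 at W₃;
   n = 13.6 at W₁ and n = 5 at W₃, interpolated linearly in W between the
   anchors (a quadratic blend is selectable; the interpolation is only
   exercised between W₁ and W₃).

   The density update is explicit Euler with dt = 0.1 d (a 0.5 d stability
   guard is enforced), dρ/dt = (mod_ob·A_ob + mod_oc·A_oc)/(ρ_ref·56 d),
   clamped to [floor, α]; a mass ledger accumulates formed and resorbed
   mass (full bone) and is conserved against the density field to 1e−9
   relative. The elasticity problem is re-solved every 1.0 d of simulated
   time (staggered coupling). Halving dt, the coupling interval or the
   mesh size changes the 56-day outcomes by less than 0.01 density
   percentage points, so the defaults are treated as converged.

## Scenario energies and the driving mode

Scenarios are collapsed to constant energy levels: sedentary W₀,
intermittent running W₁, continuous running W₃. The load multiplier is
√(W_scen/W_hom), where W_hom is the computed elastic energy of the initial
configuration under plain body weight (≈ 4.96×10⁻⁴ mJ by both FE and the
closed form), so at t = 0 the structure develops exactly the scenario
energy. The printed W₀ (3.1847×10⁻⁴ mJ) is not reproduced by any simple
closed form with the stated geometry and load; the thresholds are
therefore taken as given model inputs and the computed homeostatic energy
is used only for load normalization (`homeostatic_energy` reports the
computed value so the gap stays visible).

Two driving modes map a solved configuration to per-element energies W_e:

* **global** (default): every element is driven by the current total
  structure energy — "the energy developed within the structure". Spatial
  selectivity comes entirely from the (α − ρ)ⁿ factor, and the
  stiffness-energy feedback (forming bone lowers W toward W₀) closes the
  loop.
* **local**: W_e = W_scen·sed_e/⟨sed⟩₀, redistributing the scenario energy
  in proportion to local SED. With the tabulated parameters this mode is
  essentially inert: the formation window (W₀, W₂) is only ~17% wide in W,
  so it maps to a thin high-density shell (ρ ≳ 0.93·⟨ρ²⟩^½-scaled) where
  the modulation is already zero — measured runs change mean density by
  under 0.003%. It is kept selectable because its threshold semantics are
  the cleanest, but the global mode is the one that reproduces the
  reported dynamics; this choice of default is a deliberate design
  decision of the package.

With the global default: the sedentary run is exactly homeostatic (W = W₀
gives identically zero activity); the intermittent run gains ≈ 2.0%
volume-averaged density over 56 days with the mid-density front moving
from 0.50 to ≈ 0.49 mm and formation concentrated between the marrow and
the interface; the continuous run loses several percent with the
resorption front moving to ≈ 0.61 mm. The formation-side gain is somewhat
larger than the ≈ 1.5% the reference dynamics show, because under a
global drive the medullary region (ρ ≈ 0.15) also sits in the activation
window and fills to ρ ≈ 0.43 before the modulation self-limits; fully
localized dynamics confine the change to the interface band. This is a
known, documented bias of the global mode, not a tuning target.

## Activation delay

Continuous overload would otherwise resorb bone within days — faster than
remodeling is biologically observed. The delay presets low-pass filter
the realized (modulated) activities with a first-order lag,
a_f ← a_f + r·(a_target − a_f)·dt. The tabulated coefficients are
dimensionless and mechanism-free, so the package maps them to a rate via
r = −s/ln(c), giving slow (c = 10⁻⁵) a faster response than low
(c = 10⁻⁸). The single scale s = 2×10⁻³/d is calibrated once against the
reported delayed kinetics — the delayed run loses about 1% of mean
density over 30 days, against more than 1.5% within 7 days undelayed —
and is exposed as a module constant. Delayed runs reach the same final
density distribution as undelayed ones, only later. Elements pinned at
the density floor or at α report zero *effective* activity in the time
series (the filter state itself keeps evolving), so the global activity
curves peak and decay rather than saturating.

## Calibration

`normalized_thickness` reproduces the group ratios (1.00 sedentary,
0.74 continuous, 1.07 intermittent). `derive_w2` solves
A₁ + k₂(W − W₀) = 0 on (W₁, W₃), giving 3.716×10⁻⁴ mJ, printing as 3.72
at table precision. `derive_rate_params` converts each running group's
thickness change against the control into a net mass change per unit
volume over 56 d — the thickness change is read as an annular shift of
the interface at constant outer radius, and the shifted-profile mass
difference is integrated exactly — then solves

    C_W1 = (k₁ + k₂)(W₁ − W₀),    C_W3 = k₁(W₁ − W₀) + k₂(W₃ − W₀)

for the slopes. Fed with net rates consistent with the printed table
(+59.985 and −240.02 mg·mm⁻³·(56 d)⁻¹) this linear system returns the
printed k₁ and k₂ exactly; fed with the raw thickness table it returns
values three orders of magnitude smaller, because the printed activities
are pre-modulation intensities while thickness changes reflect modulated,
localized remodeling. The derived set is therefore always reported next
to the reference set, and the reference set remains the runtime default.
The synthetic round-trip test closes the loop: a reduced-magnitude
activity law drives modulation-free forward runs, whose mean-density
changes are converted back to thickness observations and re-derived,
recovering the generating k₁, k₂, A₁, A₂ to well within 5%.

## Synthetic fixtures

`make_fixture` generates per-element density fields for testing: the
arctan profile, radially shifted variants (translation equivariance of the
front tracker), two-ring composites (hand-computable elastic energy) and
uniform fields, plus an optional smooth seeded perturbation (low-order
radial cosines). These emulate idealized, axially uniform configurations
only — no trabecular microarchitecture, porosity distribution or
measurement noise — so passing tests certify the solver and bookkeeping,
not fidelity to µCT-derived geometries.

## Known limitations and open points

* The spatial localization of remodeling is cruder than in the reference
  dynamics (see the global/local discussion above); the medullary fill
  under the global mode is its visible artifact.
* A stated total diaphysis volume of 125.6 mm³ would imply a 2 mm outer
  radius, inconsistent with the 1.5 mm geometry used here; the geometry
  follows the stated dimensions and the discrepancy is simply recorded.
  The reported ~3 g net mass change is likewise inconsistent with a
  ~0.13 g diaphysis; the mass ledger reports mg.
* Simple compression only — no bending, torsion or stride-resolved
  loading; the exercise protocols enter solely through their identified
  energy levels.
* The activity-energy law is linear by assumption; nonlinear laws, an
  osteocyte-network (nonlocal) stimulus and under-loading (hypogravity)
  regimes are out of scope.
* Experimental fronts (e.g. a degradation front at r = 0.76 mm) mix
  experimental and model coordinate frames and are treated as comparison
  constants only, never as fitting targets.
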