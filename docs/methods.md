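# Methods

## Governing model

`scaldsim` solves the one-dimensional Pennes bioheat equation across a hot
porridge layer (x ∈ [−L, 0)) and four skin layers (x ∈ [0, Δ], Δ = 42 mm
plus the epidermis):

ρC ∂T/∂t = ∂/∂x(k ∂T/∂x) + W_b ρ_b C_b (T_b − T) + Q_met

The one-dimensional planar treatment is justified by the geometry: the heat
penetration depth over a one-minute exposure (≈ 2√(a·t) ≈ 5 mm) is far
smaller than the circumference of a forearm or thigh.  The spill is assumed
to wet the skin perfectly (no contact resistance), to arrive instantaneously
at t = 0 with a uniform temperature, and to stay in place — consistent with
the high viscosity of rice-and-milk porridge — until it is (optionally)
removed instantaneously at `t_off`.

Assumptions worth stating explicitly:

- tissue thermal properties are temperature-independent;
- no evaporative or radiative losses from the porridge surface, no
  clothing layer, no porridge flow or slumping;
- the initial skin temperature is 37 °C at all depths (conservative; it
  avoids assuming an initial gradient);
- the inner boundary at x = Δ is adiabatic.  The muscle layer is included
  so that Δ comfortably exceeds the penetration estimate 2√(a_max t) even
  at 240 s (10.7 mm ≪ 42 mm).

## Materials

Tissue layers (k in W/m·K, ρ in kg/m³, C in J/kg·K):

| layer        | k    | ρ    | C    | thickness |
|--------------|------|------|------|-----------|
| epidermis    | 0.22 | 1200 | 3600 | 40–80 μm (60 μm default) |
| dermis       | 0.40 | 1200 | 3600 | 2 mm  |
| subcutaneous | 0.20 | 1000 | 2500 | 10 mm |
| muscle       | 0.45 | 1000 | 3800 | 30 mm |

Porridge properties are quadratic polynomials in temperature (°C), valid on
[0, 100] °C, representative of rice-and-milk products:

- k_p = −6.0×10⁻⁶ T² + 0.0015 T + 0.5061 W/m·K
- ρ_p = −3.4×10⁻³ T² + 0.0377 T + 1046.6 kg/m³
- C_p = −4.0×10⁻³ T² + 0.2000 T + 3743.5 J/kg·K

All three are concave and strictly positive on the validity range, and k_p
exceeds every tissue conductivity, which is why the contact temperature is
governed mainly by the skin side.  By default the polynomials are
re-evaluated every step at the local node temperature; a config switch
(`porridge_properties: frozen`) evaluates them once at the spill temperature
for sensitivity and verification runs (the constant-property configuration
is what the closed-form contact oracle and the enthalpy-conservation test
use).

Perfusion and metabolism use textbook physiologic values: ρ_b = 1060 kg/m³,
C_b = 3770 J/kg·K, T_b = 37 °C, W_b = 1.25×10⁻³ s⁻¹ and Q_met = 400 W/m³ in
the vascularised layers, zero in the epidermis and porridge.  For exposures
up to a minute these terms shift the damage integral by a few percent; they
matter increasingly at late times (see Limitations).  All are overridable
from config.

## Damage kinetics

The basal-layer injury follows first-order Arrhenius kinetics,
dΩ/dt = P exp(−ΔE/(R T_K)) gated to zero at or below 43.0 °C, with
P = 3.1×10⁹⁸ s⁻¹ and ΔE = 6.28×10⁵ J/mol.  With these constants the rate at
60 °C is 1.06 s⁻¹, reproducing the classic equivalence of roughly one
second at 60 °C for Ω ≈ 1.  (An activation energy three orders larger is
sometimes seen in print for this frequency factor; it makes the Boltzmann
factor underflow to zero at all physiological temperatures and is a
transcription artefact of the 10⁵-scale value.  The constant is settable,
and the package treats 6.28×10⁵ J/mol as the default.)  The gate at
43.0 °C changes Ω by less than 10⁻⁴ relative to an ungated integral because
the unguarded rate at 43–44 °C is ~10⁻⁶ s⁻¹.

Ω is accumulated with a rectangle rule at the solver step (2×10⁻⁴ s); the
quadrature error is orders of magnitude below the kinetic-constant
uncertainty.  Classification: Ω < 0.53 sub-threshold, Ω ≥ 0.53 superficial,
Ω ≥ 1.0 superficial partial-thickness (depth-resolved deep-partial /
full-thickness grading would require per-depth damage profiles and is out
of scope).

## Discretisation

Cell-centred uniform grid, Δx = 10 μm by default; every layer thickness
must be an integer multiple of Δx (all default thicknesses are).  Face
conductivities between unlike cells are harmonic means 2k₁k₂/(k₁+k₂) — the
conservative choice that preserves flux continuity across material
interfaces.  Time integration is explicit forward Euler (FTCS) at
Δt = 2×10⁻⁴ s, guarded by the Fourier criterion a Δt/Δx² < 0.5 per material
(0.24 for muscle, ~0.30 for 70 °C porridge at defaults); the solver refuses
to run on an unstable step.  Convective boundaries are Robin conditions
applied as face fluxes on the boundary cell, with the film coefficient
taken in series with conduction through the outer half-cell.  A
non-conservative per-node-diffusivity scheme was evaluated and rejected: it
under-delivers interface heat flux grossly (order-of-magnitude low damage
integrals for the base case).

Verification anchors built into the test suite:

- uniform 37 °C is a fixed point; a discrete maximum principle holds with
  sources off;
- with all exchanges off, total enthalpy is conserved to better than 10⁻⁶
  relative over 10⁵ steps;
- a constant-property two-slab contact run matches the closed-form
  semi-infinite solution (effusivity-weighted contact temperature plus erf
  profiles) to < 0.2 °C over the first two seconds;
- halving Δx and quartering Δt changes the base-case Ω by ~5×10⁻⁶
  relative — the defaults are numerically converged;
- the production (numba-compiled) kernel and the transparent numpy
  reference step are pinned to agree step-for-step.

## Basal-layer sampling

The damage integral is driven by the temperature of the basal layer, i.e.
the epidermis–dermis junction at depth L_epi.  On a cell-centred grid no
node sits exactly there: the nearest candidates are the deepest epidermis
cell centre (L_epi − Δx/2) and the first dermis cell centre (L_epi + Δx/2).
The default (`basal_sampling: interface`) interpolates the junction
temperature itself from those two cells with conductivity weights
(k₁T₁ + k₂T₂)/(k₁ + k₂), which is the flux-continuous interface value; a
vertex-centred code with material boundaries on nodes would carry a node at
exactly this depth.  Both single-cell alternatives are selectable; they
bracket the interface value and move the base-case Ω by roughly ±4%, which
is one of the larger single numerical choices in the model (the damage rate
changes ~0.7 %/0.01 °C at these temperatures).

## Boundary-schedule parameters

h_air = 10 W/m²K and h_water = 600 W/m²K; water at 15 °C.  The ambient air
temperature is taken as 20 °C: with h_air = 10 W/m²K the outer-air loss is
about two orders of magnitude below the conductive flux into the skin, so
±5 °C here is inconsequential for Ω.  After removal, the same air Robin
condition applies at the bare skin surface.

## Scenario library

Nineteen built-in scenarios: the base case (3 mm, 70 °C, 60 μm epidermis,
never removed) and systematic single-parameter variations — spill
temperature 65/75 °C, thickness 2/4 mm, epidermis 40/50 μm, removal at
10/20/30 s for 70 and 75 °C, water cooling 1 s or 10 s after removal — plus
90 °C and 95 °C spills representing pot-handle accidents at processing
temperature.  One library row (P) had mutually inconsistent tabulated
source fields; its schedule follows the row's textual description (removal
at 30 s, water from 31 s).  Damage integrals for the tabulated cases are
compared at 60 s; the base case can be extended to 240 s to observe the
plateau as the spill cools below the injury threshold.

## Reproduction accuracy and known limitations

With the defaults above, 14 of the 17 tabulated reference damage integrals
are reproduced within ±15%; the exceptions are the thin-margin 65 °C case
(+15.2%), the 4 mm-layer case (+27.7%) and the 240 s plateau (+25.4%).  The
deviation pattern correlates with how much of each case's damage accrues at
late times, i.e. with the strength of the late-time heat sink.  The
dominant unconstrained input is the perfusion model: the reference values
for W_b and Q_met behind the published table are not recoverable, and skin
blood flow in reality ramps up with roughly a 20 s delay under heating — a
thermoregulatory response this package deliberately models as a constant
physiologic perfusion instead.  A sensitivity study (doubling and
quadrupling W_b) compresses the late-time overshoots but pushes the
early-removal cases out of band, confirming that no constant perfusion rate
reproduces every tabulated value simultaneously; the constant default is
therefore retained rather than calibrated.  Other simplifications: no
evaporative cooling of the porridge surface (would selectively cool thick
layers at late times), perfect thermal contact, and temperature-independent
tissue properties.

## Performance

The production path advances ~4500 nodes over 300 000 steps per 60 s case
in a few seconds (numba-compiled kernel; static tissue face conductances
precomputed, porridge faces refreshed per step).  The numpy reference step
exists for transparency and testing, not speed.
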