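# Methods

This note documents the models implemented in `cocoadry`, the choices made
where the design was genuinely open, and what the synthetic tests do and do
not demonstrate about real drying experiments.

## Scope and model structure

The package analyses forced-convection drying of a single fermented CCN51
cocoa bean. Four model layers:

1. **Thermophysical properties.** Each tissue (testa shell, cotyledon core)
   is a mixture of water, protein, fat, carbohydrate, fiber and ash. Pure
   components follow the Choi–Okos above-freezing polynomials; mixtures use
   ρ = 1/Σ(Xᵢ/ρᵢ), Cp = ΣCpᵢXᵢ, k = ΣkᵢVᵢ, α = k/(ρCp), with mass fractions
   Xᵢ and volume fractions Vᵢ = (Xᵢ/ρᵢ)/Σ(Xⱼ/ρⱼ). Quadratic correlations in
   T are fitted over 40–70 °C, the drying interval.
2. **Geometry.** The bean is idealized as a prolate spheroid, 22 mm × 12 mm,
   with a 0.55 mm shell, axisymmetric about the major axis. The mesh is a
   structured triangle mesh: a constant-normal-offset band for the shell and
   a graded polar fan for the core, built so triangles stay non-obtuse
   (M-matrix stiffness → discrete maximum principle).
3. **Transport.** Transient heat conduction and Fickian moisture diffusion
   in the solid, with temperature-dependent ρ, Cp, k per subdomain and an
   Arrhenius effective diffusivity Deff = D₀ exp(Ea/(R·T)), D₀ = 12×10⁻⁴
   m²/s, Ea = −38 kJ/mol, R = 8.314 J/(mol·K). (The frequently-quoted
   R = 8314 J/(mol·K) alongside Ea in J/mol is dimensionally inconsistent
   and would give Deff ~ 10⁻³ m²/s; the solver rejects such combinations.)
   No external flow is solved: film coefficients come from the sphere
   correlations Sh = 2 + 0.552 Re^0.53 Sc^(1/3) and its heat analog with Pr,
   using the volume-equivalent sphere diameter (≈14.7 mm) as the
   characteristic length. The far-field vapor concentration is the ambient
   air's (26 °C, 72% RH) vapor content re-expressed at chamber temperature
   (≈0.90 mol/m³ at 50 °C).
4. **Kinetics.** Volume-averaged moisture is reduced to a moisture ratio
   MR = (c̄ − ce)/(c₀ − ce) and fitted by the diffusion-approximation model
   MR = a·e^(−k₀t) + (1−a)·e^(−k₀bt). The printed form of the MR definition
   with (c − c₀) in the numerator gives MR(0) = 0, contradicting the model's
   MR(0) = 1; the standard normalization is used.

## The evaporative surface closure

The semiconjugate mass boundary condition −D ∂c/∂n = hm (c − c∞) mixes a
solid-phase concentration (c₀ = 10,878 mol/m³) with a vapor-side film
coefficient and a vapor-phase far field (≈0.9 mol/m³). Taken literally it
implies surface fluxes hundreds of mol/(m²·s) — far beyond what air can
carry — and collapses the surface concentration within seconds (mass Biot
≈ 3×10⁸), producing a spurious √t flash-drying transient. Two closure
decisions follow:

- **Vapor-side saturation limit.** The surface mass flux is capped at
  hm·(c_sat(T_s) − c∞), the carrying capacity of saturated air at the
  surface temperature (water activity taken as 1; sorption isotherms are
  out of scope). Implemented as a per-node Robin coefficient
  hm_eff = min(hm, cap/(c_s − c∞)) lagged one time step, which preserves
  linearity, the M-matrix structure and exact discrete mass conservation.
  While the cap binds (the first ~10 min) the bean dries at the classic
  constant-rate (wet-bulb) period; afterwards internal diffusion limits and
  the plain Robin condition is recovered.
- **Latent-heat mass basis.** The nominal c₀ under-counts the bean's water:
  composition and geometry give ≈1.1 g of water, i.e. ≈0.060 kg per
  model-mole rather than 0.018. The latent sink on the heat equation is
  λ·m_cal·(molar flux) with m_cal = (initial water mass)/(c₀·V) by default
  (`latent_basis="inventory"`), so the energy debited matches the enthalpy
  of the water that actually leaves; the literal molar basis is available
  as `latent_basis="molar"`. λ = 2.38×10⁶ J/kg (water near 50 °C).

With this closure the energy balance also bounds the surface temperature:
convective heating at the initial 24 °C always exceeds the capped
evaporative sink for air temperatures in 40–70 °C, so the solution respects
T ∈ [T₀, T_air] and c ∈ [c∞, c₀] to round-off.

## Numerics

- Axisymmetric P1 finite elements with the 2πr revolution weight; the
  stiffness integrand is exact under centroid quadrature (linear in r).
  Mass and Robin operators are row-sum lumped.
- Backward Euler by default (unconditionally bound-preserving on this
  discretization); Crank–Nicolson (θ = 0.5) is available for smooth
  problems and is verified at order ≈1.9, but it oscillates on the steep
  early moisture front at large Δt — the runtime bounds guard aborts such
  runs rather than returning unphysical fields.
- Properties and Deff are lagged one step; operators are reassembled (and
  the sparse LU refactored) when the temperature field drifts more than
  0.25 °C since the last assembly, or whenever the saturated Robin
  coefficient changes. An optional Picard loop iterates the properties to
  1×10⁻⁶ within a step; over the 24→50 °C span lagging is accurate and much
  cheaper.
- Discrete water conservation is exact by construction (the stiffness has
  zero row sums and the audit uses the same boundary operator as the
  solve); the audit reports ~10⁻¹⁴ relative error.
- Default production resolution: 0.5 mm target mesh size with 3 shell
  layers (~1,100 nodes), Δt = 5 s, 350 min horizon, traces every 60 s. The
  50 °C core-temperature plateau changes by <0.01 °C on a 2.6× finer mesh
  with half the step. A full run takes a few seconds; verification tests
  use coarser meshes and shorter horizons (stated in each fixture).

## Verification

- **Sphere oracle.** For a uniform-property sphere with constant Deff the
  problem reduces to Robin-boundary diffusion; the volume-mean is compared
  against the eigenfunction series (eigenvalues by root bracketing,
  coefficients by quadrature — independent of the FEM code). Agreement is
  within 0.15% of the initial span after 5 min; the suite requires <0.5%.
- **Convergence.** Observed spatial order ≈2 (volume-mean error under mesh
  refinement), temporal order ≈1.1 (backward Euler) and ≈1.9
  (Crank–Nicolson) by Richardson comparison.
- **Round trips.** Noise-free kinetic fitting recovers generating constants
  to ~10⁻⁴ relative from a deterministic 3×3×3 multi-start grid (the model's
  (a,b,k₀) ↔ (1−a,1/b,k₀b) symmetry is resolved by reporting a ≤ 0.5).

## Synthetic experiments

The virtual oven reproduces the laboratory protocol: one bean of 1.973 g
initial mass (dry matter 0.700 g, initial moisture 1.82 g/g dry basis),
weighed every 20 min on a 0.001 g balance over 350 min, plus a core
thermocouple trace. Measurement noise is additive Gaussian on mass
(default σ = 0.002 g, a conservative stand-in for handling variability the
study does not report) and on temperature (σ = 0.2 °C), with balance
quantization applied after the noise. One integer seed drives all streams
through separate `SeedSequence` spawns and is serialized with every output.

What these emulations do **not** capture: moisture re-absorption during
weighing, bean-to-bean variability in size and composition, shrinkage
(8–12% is observed experimentally but excluded from the model), and any
departure of real film coefficients from the sphere correlation (real beans
sit partly in a wake). Passing the recovery tests therefore demonstrates
the statistical soundness of the pipeline under the protocol's sampling and
noise, not the field accuracy of the transport model.

### An identifiability limit worth knowing

At the 20-min weighing cadence the fast mode of the 50 °C model
(k₀ = 0.082 min⁻¹) has decayed to 19% by the first sample. With noise at
~1% of the moisture-ratio scale, k₀ is statistically unidentifiable from a
single run (median deviation ~12%, occasional order-of-magnitude outliers),
while the amplitude a remains stable. With the protocol's realistic balance
noise (~0.16% of scale) all three constants are recovered within a few
percent. The suite tests both regimes.

## Known limitations

- The quasi-steady core temperature at 50 °C/1 m/s computes to ≈46.4 °C
  (median over 60–240 min) against the experimentally reported 44 °C.
  The discrepancy is structural: once internal diffusion limits the drying
  rate, the latent sink can no longer hold the bean ~6 °C below the air
  temperature — sustaining 44 °C through 240 min would require evaporating
  more water than the bean still contains at that point under this film
  model. The trace passes through 44 °C near 100 min and relaxes toward the
  air temperature as drying completes.
- Two-exponential fits to the simulated 40–70 °C drying curves achieve
  R² ≈ 0.9995–0.99991 and RMSE ≈ 0.0014–0.0052: the effective diffusivity
  grows several-fold during the evaporation-cooled warm-up, so the decay is
  not exactly a sum of two exponentials. The fitted optimum was confirmed
  global by a dense random multi-start.
- Composition-based thermal conductivity of the testa (0.380 W/m·°C) sits
  ~11% below the published tissue value (0.427); the cotyledon matches to
  0.1%. No standard mixing rule reproduces the published testa value, so
  the simulation defaults to the published quadratic correlations while the
  composition path reports the Choi–Okos result.
- Single-domain comparisons homogenize by volume-weighted property curves;
  enthalpy-weighted alternatives would differ at the ~1% level.
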