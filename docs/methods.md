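# Methods

## Model structure

The fruit is a triaxial ellipsoid (semi-axes H ≥ W ≥ w) with a concentric
ellipsoidal stone and a 1 mm peel, discretised on a uniform Cartesian voxel
grid: a voxel belongs to the fruit iff its centre lies inside the ellipsoid,
and to the stone iff its centre lies inside the stone ellipsoid. The target
of "more than 800 sub-units" balances spatial resolution against the
quadratic cost of the explicit timestep in 1/Δx²; the builder shrinks the
spacing until the count strictly exceeds the target. Because the voxel
pitch (≈8 mm for a mature fruit at ~850 cells) exceeds the peel thickness,
surface cells carry a peel *volume fraction* `min(1, t·S_exposed/Δx³)` and
their K, Cp and Sg are the volume-weighted mix of peel and pulp.

A staircase surface overestimates the true area (by ~50 % for axis-aligned
voxels), and every boundary flux is proportional to the face area S, so all
exterior face areas are rescaled by a single global factor that makes their
sum equal the analytic (Thomsen, p = 1.6075) ellipsoid area. Interior faces
are left at Δx²: interior conduction is a consistent finite-volume operator
on the uniform grid and must stay antisymmetric pair by pair.

The sunny and shaded sides are fixed hemispheres, split by a configurable
vertical plane through the fruit centre: a face is "sunny" iff its centroid
lies on the sun side. (Classifying by outward face normal instead would put
only beam-facing axis-aligned faces on the sunny side and break the
half/half split a convex fruit must have; the hemisphere reading also
matches the two-compartment picture of sunny and shaded peel.) Each side
has its own shortwave reflectance `A_sw` and skin conductance `Gw`; incident
shortwave on the shaded side is a flat 20 % of global radiation, while
sunny faces receive diffuse radiation (configurable fraction, default 0.15)
plus the direct beam weighted by the face-normal/sun cosine. The sun
direction is a fixed configurable vector (azimuth + elevation); a simple
declination/hour-angle helper is provided, a full solar-position algorithm
deliberately is not.

## Fluxes and integration

Signs are positive into the fruit. Transpiration uses the dew-point
linearisation `es(Ts) − ea ≈ Δ(Td)·(Ts − Td)` — the single most
consequential notational choice in the model — and is clamped at zero for
Ts < Td (no condensation; a flag allows signed flux). Air density is
CIPM-2007 moist air; saturation pressure and its slope are Buck (1981)
over water, with the slope taken analytically. The convective coefficient
uses the Whitaker sphere correlation with the viscosity-ratio factor set
to 1 (surface and bulk air are within a few kelvin) and film properties
from a small built-in dry-air table at (Ta + mean surface T)/2; the
characteristic length is the volume-equivalent sphere diameter.

The update is forward Euler in flux form. The timestep is
`safety · min[(ρCp)_min Δx²/(6 k_max), min_b ρCpV/(h_tot S_b)]` with
safety 0.5 by default; `h_tot` bounds the linearised surface exchange
(convective + radiative 4εσT³ + transpiration GwρCp_airΔ/τ, evaluated at
weather maxima plus margin). Interior conduction uses the series
(harmonic-path) interface conductivity and is scattered `+F/−F` per face,
so the global interior exchange sums to round-off zero; the energy audit
(enthalpy change vs time-integrated boundary power, normalised by the
integral of absolute fluxes) therefore sits at ~10⁻¹⁵ for full runs, and
any regression in the flux bookkeeping surfaces immediately.

Hourly weather is linearly interpolated to each solver step (~20 s). The
initial field is uniform at the first record's air temperature unless a
value or per-cell field is given.

## Growth and development

Growth keeps the sub-unit count and topology constant and scales all linear
dimensions, so volume and area scale exactly as s³ and s²; the mesh stores
its base geometry plus a cumulative scale factor, making repeated growth
associative to the bit. Development schedules (per-stage water content,
density, Gw, A_sw and height scale at DAB 60/90/120/130, linearly
interpolated between stages) are applied once per simulated day at
midnight: the daily timescale is three orders of magnitude slower than the
thermal one, and discrete updates keep the energy audit exact between
updates (the enthalpy jump at each update is logged and excluded from the
audit). Peel fractions are recomputed from the unchanged absolute peel
thickness and the grown Δx.

## Parameters and defaults

| parameter | default | notes |
|---|---|---|
| emissivity ε | 0.94 | peach-skin value, reused for mango |
| A_lw | 1 − ε | Kirchhoff |
| K(xw) | 0.148 + 0.493·xw W m⁻¹K⁻¹ | linear in water mass fraction; configurable |
| Cp(xw) | 837.4 + 3349·xw J kg⁻¹K⁻¹ | Siebel above-freezing; endpoint ≈ 4186 at xw = 1 |
| τ | 66.5 Pa K⁻¹ | psychrometric constant |
| Cp_air | 1004 J kg⁻¹K⁻¹ | constant |
| L_vap | 2.25×10⁶ J kg⁻¹ | constant vaporisation enthalpy |
| Gw | 4.4×10⁻⁴ (sunny) / 5.2×10⁻⁴ (shaded) m s⁻¹ | mature-stage defaults |
| A_sw | 0.478 (sunny) / 0.511 (shaded) | mature-stage defaults |
| peel thickness | 1 mm | constant over development |
| stone/fruit axis ratios | 0.85 / 0.45 / 0.30 | placeholder, cultivar-specific, configurable |
| shaded shortwave fraction | 0.20 | of global radiation |
| diffuse fraction | 0.15 | clear-sky default |
| CFL safety | 0.5 | of the critical step |

The stone-dimension ratios and the K(xw) coefficients are configuration
with documented placeholders because no printed values exist to anchor
them; every defaulted coefficient is echoed into the run metadata.

## Synthetic data

The weather generator emulates a tropical growing-season station record:
air temperature follows a piecewise half-cosine with its minimum at dawn
(06:00) and maximum mid-afternoon (15:00), relative humidity is in
anti-phase, global irradiance is a half-sine over the daylight window
(peak 900 W m⁻²), and wind is constant (1.5 m s⁻¹) with optional seeded
Gaussian noise. Defaults of 16–30 °C and 40–90 % RH describe a warm coastal
season. It does **not** reproduce cloud passages, synoptic variability,
rain, or day-to-day irradiance changes, so tests passing under it
demonstrate the model's internal physics and its qualitative developmental
directions, not agreement with any particular field season.

The built-in mango development schedule is likewise synthetic: stage-to-
stage changes follow the measured *relative* statements for a well-exposed
mango (sunny Gw 19.3 % below shaded at mid-development, reflectance rising
27.8 %/13.8 % on the shaded/sunny side toward ripeness, pulp density
+5.6 % and stone density −2.9 % overall with a +14.8 % stone excursion,
conductivity and heat capacity falling by less than 20 %, height +46.13 %),
anchored to typical absolute values for a fleshy drupe.

## Verification and experiments

* **Sphere benchmark.** The full solver runs a homogeneous sphere
  (R = 4 mm, Biot = 0.2) under constant convective heating with radiation
  and transpiration disabled, and is scored against the eigenfunction
  series (roots of 1 − ζ·cotζ = Bi; tail < 10⁻⁸ K at 80 terms) at the
  actually-sampled radii — the mean boundary-cell radius and the centre
  cell's radius — over five lumped time constants. At ~800 cells this
  gives RMSE ≈ 0.037 K and R² ≈ 0.9997, improving monotonically with
  refinement. The density, unstated in the benchmark definition, is
  1000 kg m⁻³ in both solver and series, where it only sets the common
  time scale. R² is the squared Pearson correlation (an explained-variance
  variant is available by flag).
* **Sensitivity.** One-at-a-time ±20 % perturbations of Cp, A_sw, Sg, Gw,
  K, peel thickness, stone/fruit ratio and fruit size (all semi-axes
  jointly), central coefficient `[(out₊ − out₋)/out₀]/0.4`, outputs being
  min/mean/max temperature at the centre and both surfaces plus maximum
  per-side transpiration. Failed perturbed runs flag their rows rather
  than abort. The transpiration/Gw coefficient is structurally 1; the
  computed value (~0.96) sits slightly below because raising Gw cools the
  surface by ~0.1 K and the vapour-pressure-deficit term shrinks
  accordingly — an honest model feedback at these transpiration rates.
* **Development experiment.** Season-long runs (DAB 60–130) in which size,
  Gw, A_sw or the thermal parameters are frozen at their initial values
  one at a time. Under synthetic weather, fruit expansion dominates total
  seasonal water loss (~0.53 L evolving vs ~0.33 L with size fixed at
  ~850 cells) while the seasonal mean temperature changes by < 0.2 K —
  the developmental directions the model is meant to expose.

## Numerical choices and degenerate inputs

Eigenvalues are bracketed per π-interval and solved by Brent's method to
1e-14. The dew point is the analytic inversion of the Buck curve (RH = 0 is
rejected as undefined). Zero-variance series in the goodness-of-fit return
NaN for R² rather than failing. A mesh with no boundary faces or zero
surface exchange takes the interior-only CFL bound. A uniform transpiration
field degenerates the rate distribution to a single unit-mass bin.
Temperatures leaving a plausibility envelope (min air −15 K, max air
+25 K) warn but do not abort.

## Limitations

No canopy radiative geometry, no fruit–stem conduction, no metabolic heat,
no water-balance feedback on Gw, no continuous (sub-daily) growth, no
implicit integrator, and a fixed sunny/shaded split rather than a moving
sun. Problem sizes in the shipped tests (≈800–6400 cells, one synthetic
day for sensitivity, one 70-day synthetic season at ~850 cells for the
development experiment) were chosen as the package's standard desk-scale
configuration; all are configurable upward.
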