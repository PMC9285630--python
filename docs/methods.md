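# Methods

## Model overview

`mangromorph` simulates the coupled evolution of a muddy cross-shore
profile and a mangrove forest. The guiding assumptions: alongshore
uniformity (a 1D profile represents an open coast or broad embayment); a
single semidiurnal tidal constituent; pure cohesive sediment with an
unlimited erodible bed; vegetation influences flow only through drag and
roughness (no organic accretion, no subsurface elevation change, no wave
damping by canopies); and mangrove demography reducible to per-cell
cohorts driven by two environmental statistics — the monthly relative
hydroperiod P and the annual 90th-percentile bed shear stress τ₉₀.

## Hydrodynamics

Depth-averaged continuity and momentum are solved on a staggered grid
(water levels at cell centers, velocities at faces) with a semi-implicit
θ-scheme (θ = 1 by default, θ = 0.5 for dispersion-accurate test cases):
the free-surface gradient and the flux divergence are treated implicitly
through a tridiagonal system, friction and the vegetation sink
semi-implicitly (Picard linearization in |u|), and optional momentum
advection explicitly with upwinding. The scheme is well-balanced
(lake-at-rest exact) and conserves volume to machine precision in
closed domains; drying clips are accumulated for the mass audit.

* Seaward boundary: prescribed water level
  `η_b(t) = offset(t) + (TR/2)·sin(2πt/T_M2)`, T_M2 = 12.42 h (the
  physical M2 period; configurable). Landward boundary closed.
* Wetting/drying threshold 0.05 m; the same depth defines "inundated"
  for the hydroperiod.
* Bed shear stress for sediment and ecology defaults to the *total*
  form τ = ρ g u|u|/C_n² (all drag at the bed). The alternative "bed"
  partition computes a grain stress with the bare-bed Chézy C_b, i.e.
  vegetation form drag is not transmitted to the bed. The choice is a
  config switch; the total form is the default because the partition
  used by the reference trachytope implementation is not documented.

## Waves

A quasi-steady cross-shore energy balance stands in for a full surf-zone
roller model (it is a stand-in, not a reproduction): energy flux E·c_g
is conserved landward, a bore-type limiter caps Hs at γh (γ = 0.73) and
routes the excess flux into a roller balance d(2E_r c)/dx = D_br − D_r
with D_r = 2gβE_r/c (β = 0.10); the radiation-stress gradient
−dS_xx/dx forces the momentum equation and the near-bed orbital
velocity (linear theory) yields τ_w = ½ρf_w U_w² with a Swart-type
friction factor over a hydraulically smooth mud bed (z0 = 2·10⁻⁵ m,
f_w ≤ 0.3). The wave field is refreshed every 10 hydrodynamic steps
(quasi-steady small waves). Current and wave stresses combine linearly
by default (Soulsby's nonlinear mean available).

Known limitation: the driver carries no wave-induced mass flux (Stokes
drift / undertow) and no wave asymmetry, so the onshore pumping by which
small waves build the upper platform in full roller models is absent.
Consequently waves in this model redistribute sediment from the upper
flat into newly flooded accommodation (Zone 2) rather than enhancing
upper-flat (Zone 1) deposition; the corresponding qualitative comparison
in the acceptance suite fails and is documented as a known gap.

## Mud

Partheniades–Krone exchange: erosion M_e(τ/τ_ce − 1) above
τ_ce = 0.2 N/m²; deposition w_s·c·max(1 − τ/τ_cd, 0) with
τ_cd = 1000 N/m² (deposition effectively always active). Suspended mud
is transported by first-order upwind advection and diffusion of the
depth-integrated mass; settling is implicit so it cannot overdraw the
suspended inventory. Defaults (config-exposed, typical mudflat values):
M_e = 10⁻⁴ kg/m²/s, w_s = 5·10⁻⁴ m/s, ρ_dry = 500 kg/m³, K = 1 m²/s.
Bed updates are MORFAC-accelerated (factor 30, giving a 15-min
morphological step on the 0.5-min hydrodynamic step) and fed back to the
flow instantly. The bed is an unlimited mud reservoir. The per-year mass
ledger closes to better than 0.1 % of the gross boundary flux
(MORFAC-adjusted bookkeeping).

## Vegetation

All trees recruited into a cell in one year form a cohort sharing
diameter, height and stress history. Parameter defaults (the
*A. marina* set): G = 12.68 cm/month, b₂ = 43, b₃ = 0.536 cm⁻¹,
D_max = 40 cm, H_max = 1000 cm, fitness (a,b,c) = (−8, 4, 0.5),
competition slope d = −3·10⁻⁴ kg⁻¹, seedling diameter 1.37 cm, density
cap 30 per 100 m², root sigmoid slope 0.3 cm⁻¹ with at most 1000 roots,
C_D = 1.5 (stems) and 1.0 (roots), C_b = 65 m^½/s.

Scheduling within each year: colonization at ecological step 1 (using
that month's P and the previous year's τ₉₀ — for the first year, the
first month's samples stand in, so a bare profile can be colonized
immediately); growth every month by explicit Euler (within 1 % of a
daily integration over 20 years); mortality at step 12. A cohort dies
after 5 consecutive years of f·C < 0.5; dead cohorts are removed
smallest-diameter-first, one at a time with competition recomputed after
each removal, stopping once f·C ≥ 0.5 — surviving marked cohorts then
reset their counters, because the relief breaks the "consecutive" chain.
Cells that stay wet all month while perched above the seaward low-water
level are flagged stagnant (ponded water without lateral drainage):
they neither grow nor accrue mortality stress.

Roughness: each cohort contributes a stem class (height H, object
diameter D) and a root class (0.15 m high, 0.01 m diameter cylinders —
pneumatophore-scale defaults, config-exposed). For each class with
density n = m·D: emergent canopies keep C_n = C_b and add λ = C_D·n;
submerged canopies use the Baptist net Chézy
`C_n = (1/C_b² + C_D n h_v/(2g))^(-1/2) + (√g/κ)·ln(h/h_v)` and
`λ = C_D·n·(h_v/h)·(C_b/C_n)²`. Classes are combined by equal-weight
fraction averaging. The printed split of net roughness and extra
resistance is not exactly continuous at h = h_v (the jump is of order
C_D·n/2 in total resistance); the formulas are implemented as stated.
Because the Baptist depth dependence is weak for the mostly emergent
canopies simulated here, the (C_n, λ) fields are frozen within each
ecological month, evaluated at the previous month's mean wet depth.

W₀.₅ is computed, not prescribed: a 2500 m² cell packed with mature
trees whose zones of influence (R = 10·√(stem radius in m)) tile it
without overlap gives W₀.₅ = A_cell/(2R)²·W_mature ≈ 2.61·10⁴ kg. The
growth equation's leading G·D factor is the form whose annualized
maximum is ~1 cm/yr. A_cell is kept at 2500 m² on all grids, including
coarsened test grids: every density-based quantity (cap, object density
n, W against W₀.₅) normalizes per unit area, so cohort dynamics are
invariant to the choice.

## Scenarios and scheduling

Full-scale domains: 360 cells of 50 m (18 km); initial linear profiles
(slope, seaward end, landward end) = (0.00025, −2.5 m, +2 m) micro,
(0.0005, −5, +4) meso, (0.001, −10, +8) macro, with tidal ranges 1, 3
and 5 m. Boundary SSC 10/30/50 mg/L; optional Hs = 5 cm, Tp = 1 s
boundary waves; four sea-level cases (none, 29, 55, 110 cm over a
100-year horizon). The ramp shape defaults to quadratic (accelerating,
zero initial rate, RCP-like) with linear available; the switch-on is
keyed to morphological year 150 after the spin-up. Full schedule: 150
spin-up + 100 SLR years at MORFAC 30, hydrodynamic step 0.5 min.

Statistics for the ecology are sampled every 10 hydrodynamic steps
(2.5 morphological hours at MORFAC 30) — adequate to resolve P and τ₉₀
on semidiurnal cycles with bounded memory.

## Reduced-scale study conditions

Tests and desk-scale studies use 90 cells of 200 m (same 18 km span and
end elevations), a 2-min hydrodynamic step (the semi-implicit scheme
remains stable and tide-resolving), advection off on the coarse grid,
and shorter horizons: 20-year spin-ups for the slope/extent orderings;
20 + 20 years with a rate-equivalent fast linear ramp (11 mm/yr) for the
retreat comparison; and a spin-up to morphological equilibrium (250
scaled years — the no-waves system needs that long, mirroring the
purpose of the full-scale 150-year spin-up) before the slow ramp
(2.9 mm/yr, 20 years) in the wave-budget comparison. These scaled runs
reproduce orderings and signs, not magnitudes; passing them shows the
coupled feedback directions are right, not that desk-scale magnitudes
match a 250-year full-resolution simulation.

What the reduced runs do not emulate: spring–neap and overtide forcing,
storms, estuarine circulation, organic soil building, multi-species
zonation, and the wave mass-flux mechanism noted above.

## Numerical choices and degenerate inputs

Ties and edges: the mangrove seaward/landward edge is the outermost
cell with a live tree; Zone 1/Zone 2 boundaries come from intersecting
the pre-SLR profile with the high-water levels before/after SLR, and a
zone containing no cell centers is reported as degenerate rather than
interpolated. Percentiles use the linear-interpolation estimator.
Negative suspended mass after advection is clipped and logged (kept
below 0.1 % of gross flux per cycle). Non-finite solver states raise
immediately with the offending cell; a failed run returns a truncated
archive that `resume` refuses. Determinism: the model has no stochastic
elements (the seed exists for optional perturbations and evaluation
grids), so identical configurations produce bit-identical archives, and
a resumed run continues bit-identically from its checkpoint.
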