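# mangromorph

A 1D cross-shore bio-morphodynamic simulator of mangrove–mudflat coasts
under sea-level rise, for coastal scientists and eco-geomorphologists who
want to explore how tidal range, wave action, sediment supply and coastal
slope jointly control mangrove vulnerability.

The package couples three components over an 18 km idealized profile:

1. **Tidal (and small-wave) hydrodynamics** — depth-averaged shallow-water
   equations on a staggered grid with a semi-implicit θ-scheme,
   wetting/drying, Chézy friction and a vegetation momentum sink
   `M = −(λ/2)·u·|u|`. An optional quasi-steady wave/roller energy balance
   adds breaking dissipation, radiation-stress forcing and a wave bed
   shear stress (Hs = 5 cm boundary waves).
2. **Cohesive mud morphodynamics** — Partheniades–Krone exchange
   (`E = M_e(τ/τ_ce − 1)` above τ_ce = 0.2 N/m², deposition `D ≈ w_s·c`),
   advection–diffusion transport, and a MORFAC-accelerated bed update
   (factor 30) so 250 morphological years ride on ~8 hydrodynamic years.
3. **A dynamic mangrove population model** (*Avicennia marina*) — annual
   seedling colonization inside windows of opportunity
   (0 < P < 0.5 and τ₉₀ < 0.2 N/m², with P the relative hydroperiod),
   monthly diameter growth
   `dD/dt = G·D·(1 − D·H/(D_max·H_max))/(274 + 3b₂D − 4b₃D²)·f·C`,
   an inundation fitness `f = −8P² + 4P + 0.5` (optimum f = 1 at
   P = 0.25), a biomass-based competition sigmoid
   `C = 1/(1 + exp(d(W₀.₅ − W)))` with the critical biomass W₀.₅ derived
   from allometry and zone-of-influence packing, delayed mortality after
   five consecutive years of f·C < 0.5, a root-number sigmoid for
   pneumatophores, and the Baptist/trachytope mapping from stems and
   roots to hydraulic roughness.

The scenario module builds the full 72-member study matrix
(3 tidal systems × 3 boundary SSC × 2 wave settings × 4 sea-level cases)
and the metrics module computes the vulnerability diagnostics: vegetated
and unvegetated slopes and extents, seaward-edge trajectories, Zone-1 /
Zone-2 sediment budgets (cm/m), station accretion rates versus SLR rate,
and relative edge displacement including a static-profile comparator.

## Worked example

A reduced-scale micro-tidal run (90 cells of 200 m, 10 morphological
years, 30 mg/L boundary SSC, no waves):

```python
import mangromorph as mm

print(f"critical biomass W_0.5      : {mm.critical_biomass():.0f} kg")
print(f"fitness f(0.25)             : {mm.fitness(0.25):.1f}")

cfg = mm.scaled_scenario("micro", years_spinup=10)
arch = mm.run_scenario(cfg, years=10)
rec = mm.extents_and_slopes(arch, 10)
print(f"vegetated cells (year 10)   : {int((arch.veg_count[-1] > 0).sum())}")
print(f"horizontal vegetation extent: {rec.horizontal_extent_vegetated/1000:.1f} km")
print(f"vertical vegetation extent  : {rec.vertical_extent_vegetated:.2f} m")
print(f"vegetated slope             : {rec.vegetated_slope:.6f}")
```

prints

```
critical biomass W_0.5      : 26103 kg
fitness f(0.25)             : 1.0
vegetated cells (year 10)   : 10
horizontal vegetation extent: 1.8 km
vertical vegetation extent  : 0.45 m
vegetated slope             : 0.000250
```

The forest occupies the band between mean sea level and high water: with
a 1 m tidal range the vertical extent is ~0.5 m, and on the 0.00025
micro-tidal slope that band spans ~2 km of cross-shore distance — the
colonization window written directly into profile geometry. W₀.₅ is the
biomass at which a 2500 m² cell is exactly packed with mature trees'
zones of influence, the point where competition stress C = 0.5.

A command-line surface mirrors the library:

```sh
mangromorph enumerate-scenarios scenarios/   # write the 72-member matrix
mangromorph run scenarios/micro_ssc30_nowaves_none.yml -o archive/
mangromorph report archive/ -o edges.csv
```

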