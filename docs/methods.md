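# Methods

`mesohab` quantifies the vertical and horizontal extent of mesopelagic
habitat in gridded coupled physical–biogeochemical ocean projections.
This note documents the model behind each stage, the parameters that
matter, what the synthetic-field generator does and does not emulate,
and the numerical and design choices that were genuinely open.

## Habitat definition

Mesopelagic habitat is bounded above by light and below by oxygen:

- **Upper boundary** `z_u`: the depth at which downwelling PAR
  irradiance falls to a visual-predation threshold
  `I* = 0.0217 W/m²` (equivalently `0.1 µmol photons/m²/s` through the
  PAR quantum-to-energy factor of 4.6 µmol photons per joule).
  Diel vertical migrators descend below this isolume by day to escape
  visual predators.
- **Lower boundary** `z_l`: the shallowest depth at which dissolved
  oxygen first drops below a hypoxic threshold
  `[O₂]* = 63 mmol/m³ ≈ 63 µmol/l ≈ 2.0 mg O₂/L`, a level at which
  mortality can occur in midwater animals. Columns that never go
  hypoxic take the sea-floor depth as the lower boundary, and are
  flagged (`lower_is_bottom_fallback`); a configuration switch
  (`omit_fallback`) instead omits those columns from all downstream
  means, since both conventions appear in practice. Columns already
  hypoxic at their shallowest wet level are flagged `hypoxic_at_top`.
- **Vertical extent** `E = z_l − z_u` where both are defined. When the
  hypoxic boundary sits *above* the light boundary the column has no
  habitat; it gets `E = 0` and a `fully_compressed` flag rather than
  being dropped, so the habitat-lost signal stays in spatial means
  (strict omission is recoverable from the flag).
- **Horizontal habitat area**: at a reference depth (default 300 m,
  near the historical hypoxic boundary), the summed area of
  analysis-domain cells whose interpolated oxygen exceeds the hypoxic
  threshold. Cells with bottom shallower than the reference depth are
  excluded. In the ensemble report this is evaluated on the
  ensemble-mean oxygen field (as well as per member): with members of
  opposite oxygen-trend sign, per-member areas saturate at 0 or the
  full domain and their average is dominated by the oxygenating
  member, whereas the ensemble-mean field carries the loss signature.

All threshold crossings are located by linear interpolation between
the bracketing model levels, scanning downward; a profile exactly equal
to the threshold at a level returns that level's depth (deterministic
tie rule). Depth is meters, positive down, everywhere in the package.

## Analysis domain

Water cells with bottom depth ≥ 400 m (the shallow end of observed
deep-scattering-layer core depths), within 200 km of the coast (the
core of the poleward undercurrent), and between 34.5 °N and 40 °N.
Offshore distance is the great-circle (haversine) distance to the
nearest land cell center — the simplest reproducible operationalisation
of "offshore"; whether it should instead be measured from the 400-m
isobath is unresolved in the source material, so the reference point is
configurable in spirit (the mask parameters are all exposed). Cells
exactly on a bound are included (≥ / ≤). Cell areas are spherical
(`R²·Δλ·Δφ·cos φ`).

## Derived fields

- **Chlorophyll** from phytoplankton nitrogen biomass:
  `Chl [mg/m³] = P [mmolN/m³] × (106/16) × 12.011 × 0.03`
  (molar Redfield C:N, carbon molar mass in g/mol — 12.011 rather than
  12, a <0.1 % difference — and a fixed bulk Chl:C of 0.03).
- **Bulk attenuation** `k = a + b·Chl^c` (1/m) from the 0–100 m
  chlorophyll. The shipped coefficients
  `a = 0.0384, b = 0.0518, c = 0.428` are an implementer default for a
  Morel-type empirical fit and are expected to be replaced by a
  regionally calibrated fit via configuration; no test or reported
  number depends on them (threshold tests parameterise `k` directly).
- **Light profile** `I(z) = f_PAR · SW · e^{−kz}` with
  `f_PAR = 0.43` (configurable): a single column-bulk `k` applied over
  the whole column. A layer-resolved `k(z)` would require vertically
  resolved optics that the bulk formulation deliberately avoids.
- **Euphotic depth** `ln(100)/k` — the 1 %-light depth, independent of
  surface irradiance by construction.
- **Buoyancy frequency** `N² = (g/ρ₀)·dρ/dz` on level midpoints
  (positive for stable stratification with z positive down), maximum
  over the upper 100 m (main thermocline depth; the search depth is
  configurable). Density comes from a linear equation of state
  `ρ = ρ₀(1 − α(T−T₀) + β(S−S₀))`, `α = 2×10⁻⁴ /°C`,
  `β = 7.6×10⁻⁴ /psu`, which is adequate for locating and sizing the
  pycnocline maximum; a full TEOS-10 treatment is out of scope. N² is
  reported in 1/s² (occasionally mislabelled 1/s in the literature).
- **Fixed-depth extraction** (T at 150 m, O₂ at 300 m, light at 150 m)
  interpolates linearly between levels rather than taking the nearest
  level, since reference depths need not coincide with model levels;
  columns shallower than the target depth come out missing.
- **Upper-ocean integrals/averages** are trapezoidal over [0, z_max];
  columns shallower than z_max are integrated to their bottom (logged),
  and averages divide by the thickness actually integrated.

## Series statistics

Monthly 2-D fields are averaged spatially over the domain mask
(area-weighted by default; unweighted mode retained because the
appropriate choice depends on the grid — on the near-uniform cells of
the synthetic grid the two agree to rounding) and then by calendar
year. On the annual series:

- **Trends**: OLS of value on year; slope, intercept, R², two-sided p.
- **Epoch comparison**: closed windows [2000, 2030] vs [2070, 2100],
  Welch (unequal-variance) two-sided t-test on the annual values.
  Welch is the default because no variance-equality argument is
  available across epochs of a forced transient. Degenerate windows
  (both zero-variance) are special-cased (p = 1 when means agree).
- **Ensemble summary**: per-year mean and standard deviation across
  members. With three members the divisor matters: the sample form
  (n−1) is the default, the population form is available (`ddof=0`).
- **Epoch difference maps**: per-cell (late mean − early mean);
  negative values are habitat lost.

Trend inference is deliberately plain OLS — no autocorrelation
correction — matching how such projections are usually summarised;
the AR(1) noise in the generator exists precisely so users can see how
decadal persistence degrades short-window trends.

## Model-vs-observation evaluation

Free-running projections carry no temporal correlation with
observations, so records are compared statistically: the model is
co-sampled at each observation's position (nearest wet cell center —
no horizontal interpolation, since observation positioning error
dominates at km-scale grids), depth (linear), and month (nearest);
both sides are aggregated to annual means; the report gives means,
bias (sim − obs, absolute and as % of the observed mean), OLS trends,
a sub-period trend (default 2000–2013) to expose trend sensitivity to
extreme years near the window edge, and the time-mean ensemble spread
of the simulated annual values.

## Synthetic ensemble generator

The generator produces monthly fields for 2000–2100 (temperature,
oxygen, phytoplankton N, surface shortwave) on an idealised
eastern-boundary shelf grid (meridional coastline on the east edge,
tanh shelf-slope bathymetry reaching the maximum depth in the offshore
half, spherical cell areas). Its purpose is statistical: every
downstream stage must run, and imposed boundary displacements must be
recoverable.

Structure per member (`ScenarioParams`):

- **Oxygen**: `O₂(z,t) = O₂_base(z) + T·(t/100)·g(z) + noise + pattern`,
  with `O₂_base` exponential between 250 mmol/m³ at the surface and
  10 at depth, its e-folding scale solved so the 63 mmol/m³ isopleth
  sits exactly at `initial_hypoxic_depth` (default 290 m; the implied
  local gradient is 0.28 mmol/m³ per m). The trend shape
  `g(z) = tanh(z/150 m)` (normalised to 1 at 300 m) concentrates the
  signed trend `T` (mmol/m³/century) at depth. Because the base
  profile steepens as the isopleth shoals, the mapping from `T` to
  boundary displacement is nonlinear; `oxygen_trend_for_epoch_shoaling`
  inverts it exactly (Brent solve on the analytic profile), and
  `hypoxic_isopleth_depth` is the closed-form oracle tests check
  against. Negative oxygen values arising from extreme parameters are
  clipped at 0 and counted.
- **Temperature**: exponential profile anchored at 8.81 °C at 150 m,
  linear warming whose rate parameter is defined at 150 m with an
  e-folding decay (300 m) away from the surface, a seasonal cycle, and
  AR(1) interannual anomalies.
- **Phytoplankton**: the base chlorophyll is *inverted* from
  `initial_upper_light_depth` (default 187 m) through the k–Chl
  relation, then converted to nitrogen biomass; a fractional trend per
  century (`chl_trend`, default −0.29, set so the light boundary
  deepens ≈ 2 m between the epoch windows), a spring-bloom seasonal
  cycle, AR(1) fractional anomalies, and optional marine-heatwave
  years with multiplicative chlorophyll suppression (default 30 %) and
  a surface temperature bump — the mechanism by which reduced
  attenuation deepens the light boundary during heatwaves.
- **Interannual noise** is AR(1) with ρ = 0.5 at annual resolution,
  shared across the domain, so the annual domain-mean series carry the
  decadal-scale persistence that confounds short-window trends.
- **Horizontal structure** is a fixed smooth cross-shore pattern
  (mean-zero): ±0.2 °C on temperature, ±6 mmol/m³ on subsurface
  oxygen (tilting the hypoxic isopleth ~±20 m deeper offshore),
  ±5 % on chlorophyll. This gives the boundary fields realistic
  cross-shore spread — in particular a nonzero early-century habitat
  area at 300 m — without pretending to dynamics.

The default three-member ensemble emulates projections with two
deoxygenating members and one member whose subsurface oxygen
*increases* (the equatorial-undercurrent-strengthening analogue):
epoch-window shoalings of +93, +81 and −59 m respectively, chosen so
the member-level late-century extents bracket the ensemble-mean
behaviour (mean shoaling ≈ 38–45 m depending on noise realisation)
and so late-century ensemble spread of extent far exceeds the
early-century spread. All fields are float32, NaN below the sea floor
and on land, and bit-reproducible for a fixed seed.

What the generator does **not** emulate: advection and upwelling
dynamics, water-mass structure, vertical migration of the oxygen
minimum, spatially coherent noise, realistic chlorophyll magnitude.
On the last point: with the shipped k–Chl coefficients, the
chlorophyll consistent with a 187 m light boundary is far below
observed coastal values (~0.005 vs ~1–10 mg/m³), because those
coefficients describe upper-ocean attenuation while a 187 m isolume
implies much clearer water at depth. The generator prioritises the
boundary depths, which are the analysis target; absolute chlorophyll
(and hence the depth-integrated chlorophyll metric) should be read as
an internally consistent index, not a realistic concentration.
Consequently, passing tests demonstrate that the *machinery* recovers
imposed signals under the assumed statistical structure — not that
real projections have that structure.

## Numerical choices and degenerate inputs

- Crossing search assumes missing values (NaN) only below the sea
  floor; columns with fewer than two wet levels return not-reached
  with a warning. Interpolation is linear everywhere; the
  interpolation error of a crossing is bounded by level spacing times
  local profile curvature (≈0.2 m for exponential light at 5-m
  spacing; tests enforce ≤0.5 m).
- Non-monotone light profiles are a contract violation (the optics
  model guarantees monotonicity) and raise an error naming the cell.
- Entirely unstable columns return their (negative) maximum N² with a
  warning rather than failing.
- Constant annual series get slope 0 and R² 0.
- An empty domain mask is allowed and logged, not fatal.
- Seeds: every stochastic component (member noise, pseudo-observation
  sampling) derives from an explicit integer seed; two runs with equal
  configuration hashes produce byte-identical CSV outputs.

## Problem sizes

The generator's spatial default is 40×60 cells at ~10 km spacing with
65 vertical levels (10 m to 400 m, 25 m below). The bundled pipeline
demo and the test suite run on smaller grids (24×36 and 10×12 cells,
same vertical grid, full 101-year monthly record) — the package's
choice of example problem size; all statistics are grid-size-agnostic
because they are domain means. Memory scales as
`members × months × levels × cells × 4 bytes` per variable.

## Known limitations

- Single light threshold and single oxygen threshold: no
  taxon-specific tolerances, no acoustic scattering-layer model.
- Bulk-k optics: no spectral attenuation, no diel cycle.
- Linear EOS for N²; salinity defaults to a constant.
- Nearest-neighbour co-sampling; no observation-error model beyond
  i.i.d. Gaussian noise in the pseudo-observation generator.
- The evaluation module reads flat CSV observation tables; assembling
  real observational syntheses is out of scope.
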