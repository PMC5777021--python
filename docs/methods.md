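# Methods

This note documents the models implemented in `gridspac`, their
assumptions, the parameters that matter, the numerical choices, and what
the synthetic-data tests do and do not demonstrate.

## Spatial structure and routing

The field is discretised into square cells labelled column-letter /
row-number (rows increase southwards), 25 m and 625 m² by default. The
drainage graph is deliberately restrictive: each cell drains to exactly one
of its eight compass neighbours or directly to the outlet, and may receive
at most one upstream contributor. With in-degree and out-degree both ≤ 1
the graph is a disjoint union of simple chains ("flow lines"); validation
rejects convergent pairs (`TwoUpstreamError`), loops (`CycleError`) and
chains that leave the grid anywhere but the outlet (`DanglingError`).
Simulation order is topological — sources first — with lexicographic
tie-breaking for reproducibility. Routing is single-pass within a day:
downstream cells see upstream outputs from the *same* day, and there is no
iteration to convergence across cells. Terrain slope is derived from a DEM
with Horn's eight-neighbour finite-difference operator (the GIS standard),
using mirrored padding at edges.

The packaged "Dairy North" fixture is an approximation constrained by what
is known of the real field: 30 cells whose identities come from the soil
survey's grouping table, nine flow lines, northward drainage toward the
flume corner, a 1.78 ha total area, and 800 mm French-drain pipes. The
individual arrows of the real routing map exist only graphically, so the
fixture honours the printed constraints rather than any specific arrow.
Five boundary cells (E1, G1, D2, B3, H2 in the fixture) are flagged
incomplete and excluded from spatial map output; the choice of which five
is likewise approximate, constrained to boundary cells that published
results do not report individually.

## Soil parameterisation

Measured properties (BD, SOM, TOC, TON, pH) exist at six sample points
co-located with grid cells. Spatial runs assign each cell the Euclidean
nearest sample, ties broken by lowest sample id; single-point runs use the
unweighted arithmetic mean of all samples. With the fixture's sample
coordinates (cells F1, C3, F2, H2, C4, F5) strict nearest-neighbour
assignment reproduces the survey's printed grouping at all 30 cells — cell
D6 is an exact distance tie between samples 5 and 6, resolved to 5 by the
tie rule, matching the table. The explicit grouping table remains
authoritative for fixture runs; the algorithmic path is verified against
it in the test suite.

Hydraulics come from the continuous HYPRES pedotransfer function (Wösten et
al. 1999): van Genuchten θs, α, n plus saturated conductivity from clay,
silt, organic matter, bulk density and a topsoil/subsoil flag (topsoil =
top 0.3 m here). θr is fixed at 0.01 m³ m⁻³ as in the source publication.
θs is additionally capped at total porosity (particle density
2.65 g cm⁻³) plus 0.02. Coefficients are data in a registry keyed by name,
so alternative PTFs can be added without code changes. Texture is not
printed in the survey table; the fixture default is a clay loam
(25/40/35 % sand/silt/clay) typical of slowly permeable stagnogley
grassland soils, overridable in configuration.

Profiles default to the seven printed layer thicknesses (0.1, 0.1, 0.1,
0.4, 0.6, 0.15, 0.2 m; total 1.65 m). The source table announces eight
layers but prints seven values; the seven printed values are the default
and an `eight_layer` variant (an extra 0.1 m layer under the third)
is available by configuration. Initial chemistry: organic C and N from
TOC/TON, concentration decaying exponentially below the surface layer with
a 0.3 m e-folding depth; organic C split 2 % fast / 98 % slow; initial
mineral N small (1 kg NH₄-N and 5 kg NO₃-N ha⁻¹ profile totals,
distributed in proportion to organic C). All of these are configuration
defaults, not measured values.

## The daily column model

The per-cell day proceeds: management → surface-water partition → soil heat
→ Richards redistribution with ET extraction → pipe drainage → C/N
transformations → gas emission → plant growth. Exact mass bookkeeping wraps
the whole step; the water residual (precip + upstream inflow − runoff −
drainage − ET − deep percolation − Δstorage) and the analogous N residual
are reported per cell-day and sit at ~1e-13 in practice.

**Surface partition.** Arriving water (rain plus upstream surface inflow)
infiltrates up to the lesser of the top layer's `K_sat`·dt and the
contiguous unsaturated storage from the surface downwards; the excess is
runoff. Upstream inflow joins the recipient's surface water and may
re-infiltrate (configurable). Upstream *pipe-drain* water is intercepted by
the recipient's drain network by default — it passes through to the
recipient's drain outflow without touching its soil — mimicking
French-drain interception; `drain_to_soil: true` routes it to the surface
instead. Runoff leaving a cell carries the top layer's dissolved NH₄/NO₃
concentration; drain flow carries the pipe layer's; deep percolation
leaches the bottom layer's.

**Soil water.** Mixed-form Richards equation (Celia-style) with van
Genuchten retention and Mualem conductivity, solved implicitly per
sub-step by Picard iteration on a tridiagonal system. Numerical choices
that matter:

* interface conductivity: arithmetic mean of the adjacent nodes;
* convergence: max |Δh| < 1e-8 m, with a secondary mass-based criterion
  (steps whose water-content effect is below 1e-7 m³ m⁻³ are accepted) —
  near saturation the head can wiggle at nanometre scale without moving
  any mass;
* stabilisation: chord-slope (secant) capacity replaces the derivative
  capacity when it is larger, adaptive per-layer under-relaxation (halved
  on oscillation), and a small specific storage (1e-6 m⁻¹) that
  regularises fully saturated columns — none of these change the converged
  solution, because the final θ update is computed from the converged
  interface fluxes (mass-conservative by construction);
* adaptive sub-stepping: the daily step halves on non-convergence down to
  1/256 d, doubling again after success;
* surface boundary switching: the prescribed infiltration flux is replaced
  by a ponded (h = 0, Dirichlet) surface when the flux solve fails to
  converge or ponds the surface — the saturation-excess regime — and the
  un-infiltrated remainder becomes runoff. This is the standard
  flux/head-switching treatment and is what makes heavy rain onto a
  nearly saturated profile well-posed;
* bottom boundary: zero flux by default (the site's French drains, not
  deep percolation, remove excess water); free drainage available by
  configuration.

ET demand is Hargreaves-type reference ET computed from mean temperature
and measured solar radiation (0.0135·(T+17.8)·Rs/2.45) when no measured
reference ET is supplied — daily inputs carry no humidity or wind. Demand
splits into soil evaporation (uncovered fraction, top layer) and
transpiration (canopy-covered fraction, root-weighted over the top 0.6 m
with a 0.25 m e-folding), each extracted before the Richards solve and
linearly stress-reduced between field capacity and wilting
(h = −1 m and −150 m respectively).

The water table is the top of the deepest contiguous saturated zone
(+∞ when absent). Pipe drainage is active only when the water table stands
above the pipe bottom (0.8 m): a head-linear (Hooghoudt-style) rate,
`drain_coeff`·head, capped by the drainable water (above field capacity)
between the table and the pipe, removed shallowest-first.

**Soil heat.** Explicit conduction on the layer grid with the daily mean
air temperature as surface boundary and a zero-flux base, sub-stepped for
stability. Diffusivity 0.043 m² d⁻¹ (a typical moist-soil value). Against
the analytic semi-infinite solution the annual amplitude decays within 5 %
of exp(−Δz/δ), δ = √(2D/ω).

**C/N transformations.** All rate laws are canonical first-order forms
with multiplicative response functions in [0, 1]: a Q10 temperature
modifier (Q10 = 2, reference 20 °C, capped at 1), a moisture modifier
rising from wilting to field capacity and reduced near saturation, and for
nitrification a pH modifier (0 at pH 4, 1 above 6). Decomposition of the
fast (8e-3 d⁻¹) and slow (2.5e-5 d⁻¹) organic pools releases N to NH₄ at
the pool C:N and sends 5 % of decomposed C to dissolved organic C.
Nitrification (0.1 d⁻¹) diverts a fixed 0.002 of nitrified N to the N₂O
pool. Denitrification is microbially limited: potential rate proportional
to a denitrifier biomass pool (which grows on the C consumed, 1.25 g C per
g N at 30 % yield, and decays at 0.02 d⁻¹), gated to zero below a
water-filled-pore-space threshold of 0.62, and limited by NO₃ and DOC
availability; reduction proceeds stepwise NO₃→NO→N₂O→N₂ through the
near-surface gas pools. Gas emission is first-order in each pool, damped
by R = √(AFP/φ)·f(T) ∈ [0, 1], so a saturated surface accumulates gas
rather than emitting it. These constants are calibration placeholders
exposed on `ProcessParams`; they are plausible for temperate grassland but
are not a calibrated parameter set, and no claim is made that they
reproduce any particular published simulation.

**Plant growth.** Gross assimilation = RUE (1.8 g DM MJ⁻¹) × radiation ×
intercepted fraction (1−exp(−0.6·LAI), LAI = 0.02·shoot) × temperature
ramp (4–18 °C) × water stress (realised/demanded transpiration) × N status.
Maintenance respiration 0.008 d⁻¹ of standing biomass (Q10-scaled), growth
respiration 25 % of the surplus; net growth partitioned 60/40 shoot/root.
N uptake = min(demand from new growth plus a deficit top-up, half the
mineral N in the root zone per day); plant N is capped at 6 % of dry
matter, overflow returning to surface NH₄. Root senescence (0.004 d⁻¹)
returns C and N to the fast organic pool. Grazing removes
heads × 1.5 kg DM d⁻¹ spread over the field area, never below a 150 g m⁻²
residual, and returns 85 % of intake N as excreta to surface NH₄; cutting
exports everything above the residual. The intake and excreta constants
follow common grazing-budget practice and are configuration keys.

## Synthetic data: what it emulates, what it does not

The weather generator is a two-state Markov chain (wet-given-wet 0.60,
wet-given-dry 0.35 → stationary wet fraction 0.467) with gamma wet-day
amounts (shape 0.8, scale 7.7 mm), a seasonal temperature sinusoid
(mean 10 °C, amplitude 6 °C, peak day 197) with Gaussian day-to-day noise,
and a seasonal radiation sinusoid reduced 40 % on wet days. The defaults
give ≈ 1050 mm yr⁻¹ in a mild maritime climate — the regime of the target
site — but emulate no particular station record: no autocorrelated storm
sequences, no frontal clustering beyond first-order persistence, no
temperature–precipitation cross-correlation.

Pseudo-observations are truth plus independent Gaussian noise with
Bernoulli missingness. Passing the evaluation tests therefore demonstrates
that the statistics recover known noise (RMSE → σ, ME → 0, n_pairs →
(1−missingness)·n) and that the pipeline runs end-to-end on its own
outputs; it demonstrates nothing about agreement with real flume, probe or
chamber data, which would require the measured series and a calibrated
parameter set. For the same reason the fixture's simulated spatial biomass
contrast is much weaker than a calibrated model would produce — the only
between-cell differences are the modest survey property differences —
so the spatial-R² check is framed as parameter recovery at a known
noise-to-signal ratio rather than as a claim about spatial skill.

## Design choices where the design was open

* Same-day routing: recipients see upstream outputs from the current day
  (single topological pass), not the previous day.
* Upstream drain water joins the recipient's drain network, not its soil
  (config-switchable); upstream surface water may re-infiltrate.
* RE is the mean of per-pair relative errors × 100 (a `sum_ratio` variant
  is available); CD is Σ(O−Ō)²/Σ(P−Ō)². Neither formula is universal in
  the literature, so both are documented here and fixed in code.
* Missing observations are excluded pairwise and `n_pairs` always
  reported; days with under 90 % sub-daily coverage are flagged missing
  rather than silently dropped.
* Annual maps use calendar years; leap years average over 366 days.
* All tie-breaks (routing order, sample assignment) are deterministic:
  lexicographic on cell id, lowest sample id.

## Known limitations

* Process constants are placeholders, not a calibration; absolute N₂O and
  biomass levels should be read as order-of-magnitude.
* One soil texture for all samples (the survey prints none).
* No legume N fixation, no CO₂/CH₄, no phosphorus, no phenological stages,
  no multi-species swards.
* Single-recipient routing cannot represent divergent (fractional) flow.
* Daily forcing smooths storm intensity; sub-daily dynamics are out of
  scope.
* The heat solver ignores latent-heat and moisture-coupled conduction.

## Problem sizes used in the shipped checks

The conservation check runs the full 30-cell fixture for two years
(21,900 cell-days, ≈ 30 s); oracle-equivalence and analytic-limit checks
use 5–30-layer columns over 20–365 days. These sizes were chosen as the
smallest that exercise every code path through multiple seasonal cycles.
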