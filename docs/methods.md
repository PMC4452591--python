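# Methods

## Model

The habitat model is a deterministic threshold envelope evaluated on
three nested equal-angle grids (1°, 5′, 30″; cell-centered, half-open
cells, longitudes on [−180, 180), latitudes within 40° N–40° S). The 1°
environment gates entire 120 × 120 blocks of 30″ cells; within a passing
block, a 30″ cell is suitable iff its depth Z satisfies
0 < Z ≤ Z_max(5′ cell), with Z_max = ln(PAR/I_min)/K₄₉₀. We use the
positive-downward form of the light equation; written with the sign
convention ln(I_min/PAR)/K₄₉₀ the same quantity is negative — a
convention, not a different model. The depth comparison is inclusive and
Z ≤ 0 (land/intertidal) is unsuitable: ties are measure-zero on real
bathymetry, and inclusivity keeps the corner case PAR = I_min, Z = 0
consistent (Z_max = 0, nothing suitable).

Missing data are handled asymmetrically and deliberately so: missing
T/S/NO₃/PO₄ fail the envelope (conservative — no habitat claimed without
evidence), whereas missing Ω_ara skips only the Ω criterion, mirroring
the coverage gaps of gridded ocean-carbon climatologies; the same
skipping applies inside the configurable region mask (default boxes
approximating the Indonesian Sea and the Caribbean — the underlying
analysis names the regions but no coordinates, so the boxes are
documented configuration, not science). Missing PAR/K₄₉₀ fail the light
criterion for their block.

Areas use the exact spherical zone formula on R = 6371 km, computed from
shared latitude-edge sines so that summed cell areas telescope to the
analytic band area (closure to < 1e−12 relative, asserted in tests). The
total habitat area is the sum over suitable 30″ cells; the alternative
route (1° fraction × 1° cell area) agrees to < 0.1%, the residual being
the within-cell variation of 30″ areas with latitude.

## Carbonate system

Ω_ara is solved from TA and DIC at in-situ surface T, S (0 dbar, total
pH scale) by bracketed root finding of the alkalinity balance

TA = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] − [H⁺]_T.

Constants: K₁/K₂ Lueker et al. (2000), K_B Dickson (1990), K_W Millero
(1995) converted from the seawater to the total scale via the
Dickson (1990) bisulfate and Dickson & Riley (1979) fluoride constants,
K′sp Mucci (1983), boron/salinity Uppström (1974), calcium proportional
to salinity (Riley & Tongudai) — the conventional open-ocean surface
choice. Nutrient and HF alkalinity terms are neglected; because the
−[H⁺] term is on the total scale it absorbs the bisulfate term exactly,
so the approximation error is dominated by nutrient alkalinity, well
under 1 μmol kg⁻¹ at surface-ocean nutrient levels and far below the
0.01 agreement bound we assert against the independent oracle. The root
is found with Brent's method on pH ∈ [2, 12] (xtol 1e−13): bracketed,
derivative-safeguarded and deterministic, with the returned state
reproducing the input TA to < 1e−10 relative. Implementation constants
reproduce the standard check values at S = 35, 25 °C (pK₁/pK₂
5.8472/8.9660; log₁₀ K′sp −6.19 aragonite, −6.37 calcite).

The test-suite oracle (`tests/_oracles.py`) re-derives the same
speciation term by term and solves by a three-stage dense pH-grid scan
instead of a root finder; the reference value Ω_ara = 3.386 for
TA = 2300, DIC = 2000 μmol kg⁻¹ at 25 °C, S = 35 was frozen from that
oracle before the solver was finalized.

## Inverse mode and I_min

Reef polygons are rasterized by **vertex membership** — a 30″ cell is
observed habitat iff it contains at least one polygon vertex. Interior
fill would change the observed area and is intentionally not applied;
the half-open cell convention makes edge vertices unambiguous. A 1° cell
is a reef cell when its observed fraction is > 0; derived limits are raw
global extremes over reef cells (an optional quantile-trim flag exists
for sensitivity analysis, off by default, because real-world extremes —
e.g. upwelling-elevated nutrients — are part of the signal). Monthly and
weekly scales take extremes across all time slices; weekly series exist
for temperature only, other variables fall back to monthly, then annual.
Annual ranges are therefore nested inside monthly inside weekly ranges.

I_min is *not* derived by inverting the light equation at reef cells:
charted reefs over erroneously deep bathymetry would produce
unrealistically low irradiance thresholds. Instead it is tuned: sweep
50…500 μmol photons m⁻² s⁻¹ at step 50, refine at step 10 across the
interval bracketing the coarse optimum, minimize the Euclidean ROC
distance √(FPR² + (1−TPR)²) (the standard reading of "distance to the
perfect classification point"), ties resolved toward the smaller — less
restrictive — I_min. Because only the light criterion depends on I_min,
FP counts are non-increasing and FN counts non-decreasing along the
sweep; both are asserted as invariants. The envelope and bathymetry
screens are computed once per sweep and only Z_max re-evaluated.

## Synthetic worlds

The generator emulates the input stack, not any particular ocean: smooth
fields are seeded low-order harmonic mixtures (plus a mild latitudinal
cosine for temperature), scaled so every variable spans beyond its
planted bound somewhere in the domain. Default study conditions: a
10° × 20° domain (200 1° cells, 2.88 M 30″ cells — sized for sub-minute
full-pipeline runs), planted envelope equal to the package's default
annually-averaged limits with I_min = 450, omission rate 0.10,
commission rate 0.05, land fraction 0.12, abyss fraction 0.30.

Ground truth is made exactly recoverable by construction rather than by
luck:

* every envelope bound is **inserted** at a designated reef cell (for
  Ω_ara, the cell's TA is root-solved so the bound holds exactly); all
  other reef-candidate cells are clipped strictly inside the envelope,
  so the min/max extraction returns the planted values bit-for-bit;
* shelves of ordinary reef cells are kept shallower than 80% of
  Z_max(600), so they stay suitable across the entire sweep range;
  "deep-edge" reef cells get flat shelves at exactly Z_max(I_min*), so
  they drop out one refinement step above the planted optimum (the FN
  jump); "marginal" non-reef cells get shelves at Z_max(t) for t at
  I_min* − 10…40 and at coarser steps below, so FP counts fall strictly
  through the refinement band and the planted I_min is the unique
  distance argmin. Identifiability to ±10 therefore needs the four
  near-threshold marginal cells; very small domains (fewer than ~8 shelf
  cells) degrade to a tie band that the tie-break resolves downward.
* commissions are placed over env-suitable abyssal cells, so they create
  irreducible false negatives at every I_min (the real-world
  bathymetry/charting mismatch) without disturbing the derived envelope;
  a handful of abyssal cells also carries missing TA/DIC (the
  carbon-climatology coverage gap) and out-of-range showcase values.

What passing tests on these worlds do **not** show: skill on real
climatologies (no circulation structure, no spatial autocorrelation of
real fields, land/shelf geometry is schematic, reef "polygons" are
vertex clouds inside single cells). They do show that the machinery —
nesting, envelope logic, light/depth screening, area accounting,
inverse extraction, sweep optimization — is exact on inputs whose truth
is known.

## Numerical choices and edge cases

* Half-open cells in both axes resolve every boundary-point assignment
  deterministically; exact nesting (shared extent, integer resolution
  ratio) is required and validated rather than re-aligned silently.
* `lookup_coarse` fills a missing 1° value from the nearest non-missing
  neighbor within a 1-cell radius (center-to-center distance from the
  querying fine cell, row-major tie-break), and reports missing beyond
  that. The habitat model itself does not fill: missing environment
  fails conservatively.
* Confusion counts are defined on the full evaluation grid; cells
  outside any habitat and without observations count as true negatives.
  Rates raise on degenerate worlds (no positives or no negatives).
* The aggregate-fraction denominator is the full fine block — land and
  ocean alike — applied identically to predictions and observations so
  the two presence maps are comparable.
* All randomness lives in the generator and derives from one integer
  seed (`numpy.random.default_rng`); identical seeds give bit-identical
  worlds, reports exclude timestamps, and reruns are byte-identical.

## Known limitations

Vertex-membership rasterization under-covers large real polygons (their
interiors); the carbonate solver omits nutrient alkalinity and pressure
corrections (surface-only by design); the Ω-exempt region boxes are
rectangles, not basin outlines; no temporal dynamics or reef growth —
this is a diagnostic habitat screen, not a growth model.
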