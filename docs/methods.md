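# Methods

## Estimands and model families

The unit of analysis is the HOLC-graded neighbourhood. For each siting era
(pre-1940 baseline, 1940–1969, 1970–1999, 2000–2019) and radius (5 km main,
10 km sensitivity) the pipeline derives, per neighbourhood: indicators for
any upwind fossil plant, any coal/oil plant and any peaker plant first
operational in that era; the count of upwind fossil plants; and the
present-day emissions burden — the sum of annual NOx and SO2 (2019) and
PM2.5 (2018) tons over upwind plants still operable in 2019.

Contrasts compare *adjacent* grades (D vs C, C vs B, B vs A) rather than a
common reference, because adjacent grades were more alike at baseline; the
indicator is 1 for the worse grade. Three families:

* **Prevalence ratio (PR)** — log-link Poisson on the binary outcome with
  an HC0 sandwich covariance. The Poisson/robust combination gives
  consistent relative risks for common binary outcomes where logistic odds
  ratios would overstate them. In the saturated two-group case the PR is
  exactly the ratio of sample proportions and the sandwich CI equals the
  closed-form log-risk-ratio CI; both identities are enforced in tests.
* **Incidence rate ratio (IRR)** — NB2 negative binomial on counts,
  dispersion estimated by full maximum likelihood (chosen over the moment
  estimator for reproducibility). A dispersion estimate at the zero
  boundary is flagged as the Poisson limit, not an error.
* **Geometric mean ratio (GMR)** — OLS on log burden, restricted to
  neighbourhoods with at least one operable-2019 plant upwind. Zero
  burdens can survive that restriction only via zero-imputed missing
  emissions; they are dropped from the log-linear fit with a logged count,
  since log 0 is undefined and the imputed zeros carry no magnitude
  information.

All intervals are Wald 95% on the log scale (z = Φ⁻¹(0.975)); no
multiple-testing adjustment is applied, matching the per-model presentation
of the analysis this package reimplements. Model 1 adjusts for the
pre-1940 upwind-plant flag and census region (fixed reference level:
first region present in the order Northeast, Midwest, South, West).
Model 2 adds log 1940 city population (log chosen to tame leverage; the
scale is otherwise arbitrary) and seven 1940 appraisal covariates entered
as linear scores (ordinals included — fewest parameters), complete-case
with explicit `n_dropped_missing` reporting. The robust flavour is HC0; a
city-clustered variance is a plausible alternative but is not the default
and no equivalence is claimed.

## Geometry

Wedges are 90° sectors of the radius buffer, centred on the plant's
predominant leeward direction and bounded by the intercardinal radii
(N-wedge spans math angles [45°, 135°]), polygonized at 1° arc segments
(area error < 0.01%, far below geometric noise). Exposure is
wedge-intersects-polygon on closed sets: boundary contact counts, and a
wedge wholly inside a large polygon counts, since the distance from the
neighbourhood border to such a plant is zero. All synthetic geometry lives
in a planar metre frame, so Euclidean distances are exact; real-data use
would require reprojection to an equal-distance frame (e.g. a contiguous-US
Albers) before ingest, which this package does not perform itself.

## Wind

The leeward angle atan2(v, u), in degrees in (−180°, 180°], is binned into
half-open sectors E = [−45°, 45°), N = [45°, 135°), S = [−135°, −45°),
W = the rest. Half-open boundaries make the mapping total and
deterministic; the boundary set has measure zero for continuous winds. The
mode of the twelve monthly sectors of a single reference year defines the
predominant direction; zero-speed months carry no direction and are
dropped; ties break in the fixed order N > E > S > W. Winds are sampled at
the *plant* location by nearest grid cell (no interpolation, which would
blur categorical directions); a point equidistant between cells resolves
to the lower-index cell.

## Synthetic-data generator

The generator emulates the structure of the real inputs at study scale:
196 cities of 45 graded neighbourhoods (≈ 8,800 areas, grade mix
A 5 / B 11 / C 18 / D 11 per city), four census regions, ≈ 3,300 plants
over the four eras, era-dependent fuel mixes shifting from coal towards
natural gas, lognormal emissions by fuel spanning coal (≈ 10³ t/yr NOx) to
gas (≈ 10¹), ≈ 5% missing emissions values, block-MCAR missingness of the
seven 1940 covariates at 30% and city population at 6% (mirroring the
Model-2 sample loss), and spatially smooth monthly winds (dominant
westerly mean + Gaussian-filtered anomalies) on a 25 km grid.

Cities are contiguous blocks of 12 km square cells with worse grades
nearer the centre. Each (area, era) is *seeded* with probability
baseline(era) × multiplier(grade, era); grade C is the reference, so the
multipliers are the configured ground-truth prevalence ratios. Default
baselines {1.1%, 8%, 9%, 8%} and D multipliers {1.70, 1.72, 1.20, 1.31}
reproduce the gradients and the 1–2% pre-1940 exposure prevalence of the
study this emulates. A seeded area receives 1 + Poisson(0.35) plants, so
counts are overdispersed while their mean stays proportional to the
seeding probability: the same multiplier is simultaneously the true PR and
the true IRR.

**Target-exclusive placement.** Each seeded plant is placed upwind of its
target area — the vector from the plant to a random interior point of the
area lies inside the plant's downwind wedge, at 0.2–4.5 km — and the
placement is accepted only if the 5 km wedge intersects *no other* area
(rejection sampling against a spatial index, up to 60 tries; the rare
failures are counted in the ground truth). Consequently the realized 5 km
exposure indicator equals the seeding draw: configured multipliers are
exactly the marginal contrasts, the all-multipliers-1 null is exactly
null, and the ground-truth plant-area pairs agree with the recomputed
exposure. This is a deliberate simplification: in real data one plant
exposes several neighbourhoods, which attenuates marginal contrasts
relative to any per-neighbourhood siting mechanism and correlates
neighbouring outcomes. Passing recovery tests therefore validates the
estimation chain (geometry, registry, models) under a clean design, not
robustness to shared exposures. The 10 km sensitivity wedges *may* overlap
neighbouring areas; radius monotonicity still holds and is tested.

Plant lifetimes are lognormal with configurable median (default 49 years)
and a tight spread (σ = 0.25 on the log scale); a plant retires when its
lifetime ends before the 2019 snapshot, so observed retired lifetimes are
right-truncated exactly as in a real registry — young cohorts retire
young, and the configured median is recovered on long-window (pre-1951)
cohorts. Generators per plant (1–5) share the plant's designated fuel
except for an occasional minority-fuel generator whose capacity is capped
below the majority, keeping the designated fuel consistent with the
registry's majority-capacity classification. A small share of non-fossil
plants (nuclear, renewables, baseline biomass) exercises the exclusion
rules.

The generator's GMR "truth" is not directly configured: burden contrasts
arise from plant-count differences conditional on having an operable
upwind plant, which concentrates near 1 in this design (most of the
multiplier acts on the probability of any exposure, which the restriction
conditions away). GMR estimation is therefore validated by direct
lognormal simulation at known ratios, and the pipeline's burden fits are
checked for calibration, not for a large effect.

## What the tests do and do not show

Synthetic validation covers: exact agreement of wedge exposure with a
dense point-sampling oracle (tangent cases excluded at a 2 m guard);
registry rules against enumeration and min/max oracles; closed-form GLM
identities; parameter recovery at n ≈ 5,000 areas over 200 replicates for
true ratios 1.0–2.0 (|relative bias| < 5%, CI coverage within 92–98%);
null behaviour; and bit-identical reruns (all randomness flows from one
seed through named substreams per stage). Not represented: realistic
neighbourhood shapes, shared exposure between neighbourhoods at the main
radius, spatially correlated residual siting preferences, non-MCAR
missingness, temporally varying winds, and demand- or economics-driven
siting. Real-data conclusions additionally depend on projection accuracy
and registry data quality, which the synthetic world idealizes.

## Numerical choices and degenerate inputs

IRLS for the Poisson fits runs at tolerance 1e-12; NB fits use BFGS with a
Nelder-Mead fallback and surface non-convergence in the results table
rather than raising. Separation (an outcome all-zero in a contrast group)
is flagged, not reported as a number. GMR fits refuse fewer than 10 usable
rows. All-zero-capacity plants classify by the fuel priority order with a
log record. Model-suite failures are captured per row; a run never aborts
on a single fit. Problem sizes in the default test run are scaled to a
few cities where distributional claims are not at stake; recovery and
acceptance checks use the study-scale configuration.
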