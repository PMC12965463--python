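# redwind

Upwind power-plant siting and emissions-burden analysis for historically
graded (HOLC "red-lining") neighbourhoods — a reusable, tested pipeline
with a ground-truthed synthetic-data generator.

## The problem

In the 1930s the US Home Owners' Loan Corporation (HOLC) graded urban
neighbourhoods from A ("best") to D ("hazardous", drawn in red). A central
environmental-justice question is whether those grades shaped where fossil
fuel power plants were subsequently built, and whether that left
worse-graded neighbourhoods with a heavier present-day emissions burden.

`redwind` implements the full analysis chain for that question:

1. **Plant registry** — aggregate EIA-860-style generator records to plants:
   first operation = earliest generator start; a plant is retired only when
   all generators are retired (retirement = last to retire); primary fuel =
   the fuel holding the majority of nameplate capacity, capacity ties broken
   coal > petroleum > natural gas > other; peakers = oil plants and gas
   combustion turbines; non-fossil plants excluded (baseline biomass
   excepted); siting eras pre-1940 / 1940–1969 / 1970–1999 / 2000–2019.
2. **Wind direction** — from gridded monthly zonal/meridional winds
   (NLDAS-2-style): speed ws = √(u² + v²), leeward angle = atan2(v, u) in
   degrees, binned into N/E/S/W quadrants; the mode over 12 months gives
   each plant's predominant direction.
3. **Exposure assignment** — slice each plant's 5 km (main) or 10 km
   (sensitivity) buffer into four 90° wedges and keep the downwind one; a
   neighbourhood is *exposed* when the wedge intersects its polygon.
   Outcomes per neighbourhood and era: any fossil plant, plant count, any
   coal/oil plant, any peaker, and present-day **emissions burden** — the
   sum of annual NOx, SO2 (2019) and PM2.5 (2018) tons over upwind plants
   still operable in 2019 (missing emissions zero-imputed).
4. **Contrast models** — adjacent-grade comparisons (D vs C, C vs B,
   B vs A) to limit baseline confounding:
   * binary outcomes: log-link Poisson with HC0 sandwich variance →
     **prevalence ratio** PR = exp(β),
   * counts: NB2 negative binomial, dispersion by ML → **incidence rate
     ratio** IRR = exp(β),
   * log burdens (exposed neighbourhoods only): OLS → **geometric mean
     ratio** GMR = exp(β),
   each adjusted for a pre-1940 plant flag and census region (Model 1),
   optionally plus log 1940 city population and seven 1940 appraisal
   covariates, complete-case (Model 2).
5. **Synthetic data** — a generator that emulates the study's data
   structure (grade-dependent siting multipliers as known ground truth,
   era-dependent fuel mix, lognormal emissions by fuel, smooth wind fields,
   MCAR covariate missingness) so every stage is testable without any
   external download.

## Worked example

`examples/05_full_pipeline.py` runs a reduced 30-city world end to end:

```
areas: 1350  plants: 443 included

percent of neighbourhoods with an upwind plant within 5 km:
grade         A    B    C     D
period
pre1940     0.0  0.9  1.5   1.5
1940_1969   5.3  7.9  7.4  12.7
1970_1999  10.0  5.8  7.6  10.6
2000_2019   4.0  6.1  8.5  10.6

D vs C adjusted estimates (truth: PR 1.72 / 1.20 / 1.31 by period):
  any_fossil  1940_1969    1.72 (1.14, 2.59)
  n_fossil    1940_1969    1.66 (1.06, 2.60)
  any_fossil  1970_1999    1.39 (0.91, 2.13)
  ...
```

Exposure prevalence is grade-ordered (D > C > B > A) in the post-war eras,
and the adjusted D-vs-C prevalence and rate ratios recover the multipliers
the generator was configured with (1.72 in 1940–1969), with intervals that
tighten at the study-scale default of 196 cities. The other examples
demonstrate each capability in isolation: wind binning (`01`), registry
rules (`02`), wedge exposure (`03`) and the closed-form identities of the
three model families (`04`).

A thin CLI wraps the same library:

```bash
redwind run --seed 7 --out run_out          # full pipeline
redwind simulate --seed 7 --out sim_out     # or stage by stage:
redwind build-registry --generators ... --locations ... --emissions ...
redwind build-exposure --areas ... --registry ... --wind-samples ... --radius-km 5
redwind fit --areas ... --exposure ... --covariates model1
redwind report --results ... --summary ...
```

## Layout

* `src/redwind/` — `synthetic` (generator), `registry`, `wind`, `exposure`,
  `models`, `pipeline`, `config`, `io`, `cli`
* `tests/` — unit, property and end-to-end suites
* `docs/methods.md` — model assumptions, generator design and limitations
* `examples/` — one narrative script per capability
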