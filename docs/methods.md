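# Methods

This note documents the statistical model behind `herdcast`, the defaults of
the synthetic-herd generator, and the design decisions taken where the
procedure was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The forecasting model

All predictions are univariate linear regressions expressed through the
correlation coefficient, the form used in classical zootechnical practice:

* Pearson correlation r between a marker x and a target y, with error
  m_r = (1 − r²)/√(n − 2) and reliability decided by t = r/m_r against the
  two-sided Student critical value at α (default 0.05) with n − 2 df.
  m_r is zero exactly when |r| = 1; that case is reliable by convention.
* Regression coefficient b = r·σ_y/σ_x, with σ on the n − 1 denominator.
  The reciprocal-slope identity b(y|x)·b(x|y) = r² and agreement with an
  independent least-squares fit are enforced by tests.
* Forecast rule ŷ(x) = ȳ + b·(x − x̄). A forecast table is this line
  tabulated on a grid (default: integer-rounded x̄ ± 6 at step 1, mirroring
  the printed table layout). In `linear` mode the line is evaluated exactly,
  so the grid is presentational; `nearest` mode reads the closest grid cell,
  as a printed table would be used in the barn, and warns + falls back to
  the line outside the grid.
* The combined forecast for an animal is the unweighted arithmetic mean of
  its per-marker predictions. A correlation-weighted mean would be a natural
  extension but is deliberately not the default: the protocol being
  implemented specifies the plain mean, and the combined value is then
  guaranteed to lie between the per-marker extremes.
* Forecast accuracy is 100·(1 − |F − A|/F) with the *forecast* in the
  denominator. Farm-level accuracy applies this to the mean forecast vs the
  mean realised value (the reporting convention of the approbation
  experiment); the mean of per-animal accuracies is reported separately and
  is systematically lower whenever individual residuals are non-zero.
* Rounding for display is half-up (never banker's): 1 decimal for table
  cells and regression coefficients, integer percent for accuracy. Full
  precision is kept internally; rounding happens only at rendering.

Known tension: printed forecast tables round b to 1 decimal while their
cells are computed from higher precision (one published table's cells imply
b ≈ 1.333 where 1.3 is printed). `herdcast` computes cells from
full-precision b; `RegressionCoefficient.from_slope` supports replicating a
printed table from its printed slope where that is wanted.

## 2. Selection response

Heritability is estimated as h² = 2·r(dam, offspring), the additive
expectation for a single-parent/offspring correlation, clipped to [0, 1]
with a warning when raw 2r leaves the interval. This is deliberately the
correlation instrument — not parent–offspring regression and not a half-sib
ANOVA — because the protocol's data model provides exactly one maternal
productivity record per animal. The per-generation response is the breeder's
equation SE = S·h², with S = mean(selected parents) − mean(population).
Effects on slaughter indices are obtained by linear propagation
SE_target = b·SE_liveweight, where b is the slaughter-index-on-live-weight
regression coefficient; propagation is linear, order-preserving in b, and
shrinking whenever b < 1. One generation means one application of the
equation; no overlapping-generation demography is modelled.

## 3. The synthetic-herd generator

The generator replaces unavailable farm records. One herd draw is:

1. **Longitudinal traits.** Live weight plus six body measurements at the
   seven ontogenesis ages, and the dam's live weight, drawn jointly from a
   multivariate Gaussian on the raw scale (50 variables), then clipped at
   3σ below the mean to keep masses positive (at the default coefficients of
   variation this touches ≈ 0.1% of draws and perturbs moments negligibly).
2. **Slaughter linear links.** Pre-slaughter and slaughter mass are linear
   in the three markers plus an independent Gaussian residual. Structural
   coefficients are solved from *univariate* slope targets via
   Σ_m β = (b_j σ_j²)_j, so the population regression slope of each target
   on each single marker equals its configured value exactly.
3. **Carcass composition.** Internal fat = 4.5% of slaughter mass (+noise),
   paired carcass = slaughter − fat, chilled = 98.5% of paired (+noise),
   bone = 18% and tendon = 3.5% of chilled (+noise), pulp = chilled − bone −
   tendon, half carcass = chilled/2. Additivity (pulp + bone + tendon =
   chilled) therefore holds by construction, and every component sits below
   pre-slaughter mass.

### Default calibration

* Correlation target = Kronecker product of a between-trait equicorrelation
  block (0.8, inside the reported 0.6–0.9 band) with the pooled age-pair
  live-weight correlation matrix (entries 0.4–0.9), bordered by a dam row
  (0.4 with live weights — the reported dam–offspring band is 0.3–0.5 — and
  0.3 with measurements). This matrix is positive semidefinite outright
  (minimum eigenvalue ≈ 0.02); the eigenvalue-clipping repair path (tolerance
  1e−6 on the most negative eigenvalue) exists for user-supplied
  range-assembled matrices, which are often slightly indefinite.
* Marker sds: dam weight 19.5 kg, birth weight 2.8 kg, birth withers height
  6.0 cm. Target means/sds: pre-slaughter 425.7/39 kg, slaughter 237.3/24 kg.
  With the published slopes (1.3, 11.3, 5.1 kg per marker unit for
  pre-slaughter; 0.8, 6.0, 2.8 for slaughter mass) these imply marker–target
  correlations (0.65, 0.81, 0.79) and (0.65, 0.70, 0.70) — inside the
  reported high-correlation band and comfortably above the default 0.6
  marker screen. The composition fractions put mean pulp at
  237.3·0.955·0.985·0.785 ≈ 175.2 kg, the published anchor, and imply
  pulp-on-marker slopes near the published 0.6/4.7/1.9 without modelling
  pulp directly.
* Intermediate-age means are not published; defaults interpolate a
  saturating growth profile between the birth and 18-month anchors
  (fractions 0, 0.30, 0.50, 0.66, 0.79, 0.90, 1.0 of adult gain). They are
  placeholders with realistic shape, not reported values.
* Group labels (three sire lines, three bloodlines) default to equal mixing
  with zero mean offsets; an offsets hook shifts any trait for any label,
  propagating into slaughter traits through the marker links.

`generate_parent_offspring(config, h2_true)` rewires the dam row to
h2_true/2 against live weights (0.6·h2_true/2 against measurements, kept
small to preserve definiteness) for heritability-recovery tests. Structural
slaughter links are kept as configured there: with a rewired dam row the
three univariate slope constraints can become jointly infeasible, and those
herds exist to test h² recovery, not slope recovery.

### What the generator does and does not emulate

It reproduces second moments (means, sds, correlations), known regression
slopes, carcass additivity and group structure — everything the pipeline's
statistics consume. It does **not** emulate growth-curve dynamics
(no Gompertz-type mechanism), non-Gaussian tails, measurement error of any
recording instrument, heteroscedasticity across ages, or
selection/culling during rearing. Passing tests therefore demonstrate that
the estimators recover known structure from data of this shape — not that
real herds satisfy the linear-Gaussian assumptions.

## 4. Problem sizes and tolerances

Parameter-recovery tests use herds of n = 5000, where the sampling sd of r
is ≈ 0.014 at mid-range r: pairwise correlations are checked to ±0.05
(all 1225 pairs), single configured correlations to ±0.02, the implied
pre-slaughter-on-birth-weight slope to ±0.5 around 11.3, and h² recovery to
3 Monte-Carlo sds of 2r. Directional claims (own-farm tables beat foreign
tables on a mean-shifted farm) use two 1500-head herds with a −7% shift in
live weights and −10% in slaughter anchors. Numerical identities
(reciprocal slopes, least-squares agreement) are asserted at 1e−10 / 1e−8
relative. All randomness flows through a single seeded `default_rng`; a herd
draw is a pure function of its config.

## 5. Degenerate inputs and edge cases

* Correlation needs ≥ 4 complete pairs and non-zero variance on both sides;
  descriptive statistics need ≥ 2 values. Violations raise typed errors.
* A zero-sd marker cannot carry a regression coefficient (error), but a
  zero-sd *target* simply yields b = 0.
* Selection requires a non-empty proper subset of parents; exactly one of
  `top_fraction` / `parent_ids` must be given.
* Empty marker screens warn and return an empty set rather than raising: a
  herd may genuinely offer no usable marker.
* Missing cells in delimited files are read as absent (never as zero);
  non-numeric cells raise a parse error carrying the file line number.

## 6. Known limitations

* Forecasts carry no uncertainty intervals — the protocol defines none, and
  attaching honest intervals to the arithmetic-mean combination of three
  correlated univariate regressions would require the full marker
  covariance, which the printed-table workflow discards.
* No multivariate (joint) regression on all three markers: the method is
  defined as the mean of three univariate forecasts, and the package keeps
  that definition (the generator's structural links show what a joint fit
  would estimate).
* Heritability via 2·r(dam, offspring) inherits all the biases of
  phenotypic parent–offspring resemblance (maternal environment, assortative
  mating); no genetic/phenotypic decomposition or animal model is attempted.
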