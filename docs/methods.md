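# Methods

## The valuation model

The package values eleven ecosystem services (agricultural production,
raw material, water resources, gas regulation, climate regulation,
environmental purification, hydrology regulation, soil retention,
nutrient cycling, biodiversity conservation, aesthetic landscape) on nine
land covers, including the two artificial classes man-made wetland and
built-up area. For region r, year t, cover k and service i,

    ESV(r,t,k,i) = A(r,t,k) · D · EF(k,i) · NR · SE(t) · S(r,t)

The model is linear in areas and in equivalent factors; every aggregate
(by cover, service, category, year) is an exact sum of cube cells, which
the code exploits for margins and for sensitivity analysis.

Assumptions worth stating: per-hectare service values are spatially
uniform within a cover class; adjustments act multiplicatively and
independently; services are additive (no interactions or double
counting beyond what the factor table itself encodes); negative factors
(built-up rows, paddy-field water consumption) represent disservices and
are summed like any other cell.

## Parameters

| parameter | meaning | unit | default (packaged study) |
|---|---|---|---|
| D | baseline unit value: food production of 1 hm² arable land | yuan/hm² | 3884.09, from 3406.50 × (5577.87/4891.84 rounded to 4 dp) |
| EF(k,i) | equivalent factor | — | packaged 9×11 matrix |
| NR | city/national NPP ratio | — | 1.01 (constant; yearly ratios accepted when NPP series exist) |
| SE(t) | local/national per-capita disposable income | — | 1.08, 1.08, 1.05, 1.11, 1.17, 1.21 for the six survey years |
| S(r,t) | district-year yield factor | — | packaged district table; 1 for citywide work |
| T | study-period length | yr | 22 (1996–2018) |

Conventions that matter numerically:

* **Yield-ratio rounding in D.** The local/national yield ratio is
  rounded half-away-from-zero to 4 decimals *before* multiplication
  (3406.50 × 1.1402 = 3884.09). Carrying the unrounded ratio would give
  3884.22; the rounded-ratio path is canonical because that is how the
  published transfer chain operates. The precision is configurable.
* **Half-away-from-zero rounding** is used wherever reported values are
  produced (a mean of −0.0058 prints as −0.01, not −0.00). Internal
  computation is full precision; rounding is a reporting concern.
* **Spatiotemporal factor normalizer.** S divides each district-year
  yield by the grand *mean* over all district-year cells, so the factors
  average to exactly 1 and are invariant to yield rescaling. (A sum
  normalizer over 13 districts × 6 years would shrink every factor by
  ~1/78 and is inconsistent with factors that fluctuate around 1.)
  Districts without yield data take S = 1 (logged) or an alias map can
  fan one measured district's value out to several labels.
* **Percent change with negative bases.** Change rates divide the value
  change by the *magnitude* of the initial value, CR = (v1−v0)/|v0|·100.
  For positive series this is the ordinary formula; for covers with
  negative ESV (built-up) it keeps the sign of the change itself, so a
  deepening disservice reports as negative. The annual rate ADD = CR/T
  exactly, and the land-cover dynamic index obeys K·T = change rate
  exactly; both are unit-invariant.
* **Undefined rates.** Where v(t0) = 0 (or a cover's initial area is 0
  in the tabular report), the rate is NaN, never ±inf.

## Equivalent factors for artificial covers

Seven cover rows are adopted from the expert-scored reference tables.
The two artificial rows are derived by unweighted meta-analysis:

* **man-made wetland** — per-service arithmetic mean of published
  man-made/natural unit-value ratios (blank cells excluded from the
  denominator; printed zeros count), rounded to 2 dp, times the
  natural-wetland row, rounded to 2 dp;
* **built-up** — per-service mean of published built-up equivalent
  factors, same rounding.

The packaged ratio table's published average row disagrees with the mean
of its own printed cells in four columns (CR, EP, SR, AL) — a
transcription or column-alignment defect in the source literature that
cannot be resolved from the printed material. The canonical packaged
matrix therefore carries the *published* averages (they, not the cell
means, are what the published matrix was built from), and
`ratio_mean_discrepancies` reports the four conflicts instead of silently
preferring either side. The built-up row reproduces from its study table
in all eleven services; the man-made row reproduces in the seven
arithmetically consistent columns (AP, RM, WS, GR, HR, NC, BC).

## Sensitivity analysis

SEF(k) perturbs all eleven factors of cover k jointly by a fraction δ
(conventionally ±50 %) and measures |relative ESV change| / |δ|. Under
the linear model this collapses to |ESV_k| / |ESV_total| for every
nonzero δ, which is what the code computes; tests verify the identity
against brute-force recomputation with perturbed matrices. SEF ≤ 1 is
inelastic. The sum of SEF over covers is ≥ 1, with equality exactly when
no cover contributes negatively. An explicit `total` override exists
because published decompositions are rounded per cell independently of
their published total.

The packaged sensitivity table is verifiable against the packaged
decompositions for 1996 and 2000 only: the published 2005–2018 columns
are internally consistent with ESV totals that match neither the
published per-cover nor per-service tables, and the denominators the
original analysis used for those years cannot be reconstructed. The
package does not guess; those columns are carried verbatim.

## Driving-force stage

Candidate drivers (19 socioeconomic/natural panel variables) are screened
pairwise on Pearson correlation: while any kept pair has |r| ≥ 0.75, the
pair with the largest |r| is visited and the member with the larger mean
|r| against the other remaining candidates is dropped (exact ties drop
the later column). The rule is deterministic and idempotent. VIFs
(1/(1−R²_j), statsmodels OLS underneath) are reported against the usual
threshold of 5, with perfect collinearity reported as +inf rather than an
exception — pairwise screening is intentionally blind to three-way
relations, so VIF is a required second gate. Each response is then fitted
by OLS with intercept; p-values use the t distribution with n−k−1 degrees
of freedom and stars at 0.1/0.05/0.01. A manual kept-set override exists
because published variable selections are not always reproducible from
the stated rule.

The study's own regression panel (statistical-yearbook data) is not
printed anywhere, so this stage is validated by simulation: parameter
recovery is exact in the noiseless limit, 95 % confidence intervals cover
the generator's true coefficients at ≥ 90 % over 200 seeded replicates,
and pure-noise responses reject at the nominal 5 % rate.

## Synthetic data generator

The generators emulate the study's data shapes with known ground truth,
all driven by NumPy PCG64 from an explicit seed (identical output per
seed on any platform):

* **area panels** — 13 regions × the six survey years; initial cover
  shares equal to the observed 1996 citywide composition with small
  lognormal perturbation per region; deterministic per-type exponential
  drift (built-up +2.9 %/yr, paddy −1.8 %/yr, grassland collapse, etc.)
  renormalized to the regional land endowment (856,915 hm² split
  evenly), so totals conserve exactly and negative drifted shares clip
  at zero with renormalization;
* **yield panels** — regional mean yields (default drawn uniformly from
  4000–7000 kg/hm²) with multiplicative Gaussian noise, positive by
  bounded resampling;
* **driver panels** — 7 independent anchor predictors and 12 satellites
  sharing a latent factor with one anchor (x = f + ε with
  var(ε) = 1/r − 1, giving pairwise correlation r ≈ 0.9 analytically);
  responses are a fixed linear combination of anchors plus Gaussian
  noise, with the truth returned alongside.

What the generator does **not** emulate: spatial autocorrelation between
districts, compositional covariance beyond the shared total, serial
correlation in yields, measurement error in areas, or non-Gaussian driver
distributions. Tests passing on synthetic panels therefore demonstrate
correctness of the algorithms under the stated model, not robustness of
the scientific conclusions to real-data pathologies.

Problem sizes throughout the suite are the study's own (54-record area
panels, 78-row driver panels, 200-replicate Monte Carlo), chosen because
the method is exactly a desk-scale tabular computation.

## Known limitations

* The published per-cover decompositions for 1996 cannot be reproduced
  cover-by-cover from the published citywide areas (woodland computes to
  ≈6.5 vs the published 7.13 billion yuan; river/lake ≈55.6 vs 54.97)
  even though the grand total agrees within 1 %. The original analysis
  aggregated district-level areas with district S factors that are not
  printed; the citywide reconstruction with S = 1 is the verifiable path.
* The published area table implies a total of ≈856,915 hm² while the
  stated study area is 8569 km²; the fixtures carry areas as printed
  without reconciliation.
* No GIS ingestion: areas enter as tabular panels. No discounting,
  inflation adjustment or currency conversion. NPP and income series are
  inputs, never estimated.
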