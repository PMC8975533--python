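# Methods

## The index

Policy presence is binary: a survey answer is 1 (policy in place) or 0
(absent). Items are grouped into 15 sub-indicators corresponding to the
recommended policy areas; a sub-indicator score is the weighted mean of its
items and the raw index is the unweighted mean of the 15 sub-indicator scores
("linear aggregation"). The three formulations share this two-level
architecture and differ only in the item weights:

- **unweighted** — all items weigh 1;
- **aha** — an integer 0–9 per item derived from an evidence-grading table
  over (recommendation class I/IIa/IIb/III) × (evidence level A/B/C). Only the
  endpoints of that mapping are fixed by convention — (I, A) → 9,
  (III, C) → 0 — so the shipped table interpolates lexicographically:
  (I,B)=8, (I,C)=7, (IIa,A)=6 … (IIb,C)=1, (III,·)=0. The table is an
  editable part of the schema config, and `grade_to_weight` refuses unmapped
  pairs rather than defaulting. The table is exhaustively monotone: improving
  either class or evidence level never lowers the weight.
- **informas** — non-negative real Delphi-style weights read from the schema
  config (the published weight vector is not reprinted anywhere public, so
  the shipped values are plausible, honouring the one documented anchor that
  a high tax on unhealthy foods weighs twice private workplace food
  policies).

Applying weights *within* sub-indicators and then averaging sub-indicators
equally (rather than one flat weighted mean over all 60 items) preserves the
sub-indicator architecture; the flat mode is available as
`weight_mode="flat"` for sensitivity analysis. A formulation whose weights
are all equal reduces exactly to the unweighted index (tested to 1e-12).

**Rescaling.** Raw scores are mapped affinely onto [1, 100]:
`1 + 99·(raw − min)/(max − min)`. This is the most literal reading of a
"1–100 scale" whose benchmark country is anchored at 100; because the meaning
of the lower anchor is not documented, a `proportional` mode
(`100·raw/max`) is also provided. Min-max rescaling is undefined when all
raw scores coincide; that degenerate input raises rather than returning a
constant.

**Missing responses.** A non-answer is scored as policy-absent by default
(`as_absent`), the natural reading of a policy-presence survey; the
alternative `exclude-and-renormalize` policy averages over non-missing items
only. Both are logged in output provenance; the choice matters only for
countries with missing cells (≈2% under the default generator).

**Ranks and comparisons.** Countries are ranked descending on the rescaled
score with average ranks on ties (keeps Spearman comparisons standard).
Formulations are compared by Pearson correlation of rescaled scores and
Spearman correlation of ranks.

## The diet composite

Consumption of the seven HFSS product categories (sugar confectionery,
chocolate confectionery, biscuits, savoury snacks — kg/household/year; soft
drinks, sports/energy drinks, carbonates — L/household/year) must be strictly
positive and complete. Columns are standardized with the sample (n−1)
standard deviation; a zero-variance column is an error, not a silent drop.

One common factor is extracted by **principal-axis factoring**: initial
communalities from squared multiple correlations, iterated replacement of the
correlation-matrix diagonal until the largest communality change falls below
1e-6 (cap 200 iterations; non-convergence raises with diagnostics).
Factor scores use the regression (Thurstone) method F = Z R⁻¹ λ, computed
with a pseudo-inverse so the rank-deficient perfectly-correlated case stays
defined. The factor's sign is arbitrary, so loadings are flipped to make the
mean loading positive (higher composite = more obesogenic household diet).
Maximum-likelihood extraction (`method="ml"`, profile-likelihood over
uniquenesses) is available and agrees with PAF on well-behaved data.

The composite defaults to all seven product categories; a narrower
six-category preset (`CORE_PRODUCTS`, without sports/energy drinks) is
provided because the defining product list is stated inconsistently in the
source material.

## Association models

The design is: intercept + rescaled index + (when adjusted) six subregion
indicators (Central Eastern is the reference of the seven European
subregions), GDP annual growth (%), urban population (%), and female
labour-force participation (%) — 11 columns; unadjusted models use intercept
+ index only. The **rescaled** (1–100) index is the regressor, which makes
"per index unit" effect sizes comparable across formulations. Outcomes are
analysed on the raw scale and under a natural-log transform; the data
contract requires positive consumption, so no offset is ever added and a
non-positive value is an error rather than a log1p.

Estimation is OLS with classical homoskedastic standard errors (HC3 robust
errors behind `robust=True`), t-based two-sided p-values on n − p degrees of
freedom, and t-interval CIs. Joins are complete-case: a country missing any
required variable is dropped and the drop is logged. Rank-deficient designs
raise with the offending columns named; a subregion level absent from the
data is dropped from the design with a warning instead of producing a
zero column.

Formatted reports print standard errors in parentheses with significance
stars at p < 0.01 (***), < 0.05 (**), < 0.1 (*); tidy outputs always carry
raw p-values.

## The synthetic generator

The generator emulates the three study inputs with known ground truth:

- **Responses**: latent wealth w_c ~ N(0,1); item j is present with
  probability expit(α + β_w·w_c + δ_j), δ_j ~ N(0,1) item offsets, β_w = 1 by
  default — wealthier countries adopt more policies, mirroring the observed
  wealth gradient in the rankings. 2% of cells are masked as missing.
- **Covariates**: GDP growth ~ N(2.5, 2)%, urban share ~ U(50, 90)%, female
  LFP ~ U(40, 60)%, subregion round-robin over the seven levels.
- **Consumption**: for each product, exactly the linear model the analysis
  fits — baseline + planted index effect × the rescaled index *as computed
  from the masked responses* + shared covariate effects + subregion offsets
  (scaled by the product's noise sd) + Gaussian noise, floored at 0.5 to keep
  the log models defined (a warning fires if >10% of cells floor, since that
  breaks linearity; under defaults the floor is never reached). Planted index
  effects default to the magnitudes this design is known for (soft drinks
  −2.148, carbonates −1.046 L/household/year per index unit, and analogous
  kg-scale values for foods), and per-product noise standard deviations are
  set so that coefficient standard errors at n = 38 are on the corresponding
  reported scale (e.g. ≈1 for soft drinks). Because the generator's regressor
  is identical to the analyst's, OLS is exactly conditionally unbiased for
  the planted effects — which is what makes the recovery and calibration
  checks sharp.

A multiplicative (`log_normal_outcomes`) mode exists for exercising the
logged models. Default sizes are the study conditions: 38 countries, the full
60-item schema.

What the generator does **not** emulate: real countries' identities or policy
correlations beyond the single wealth factor, measurement error in sales
data, spatial autocorrelation within subregions, or heteroskedasticity.
Passing recovery tests therefore demonstrates the estimators are correct
under the stated model, not that the published ecological estimates are
causally interpretable.

## Numerical choices and problem sizes

- Index arithmetic is exact up to float rounding; oracle-equivalence tests
  compare against independent loop-based recomputation at 1e-12.
- OLS is checked against a normal-equations solver at 1e-8 on random
  n=38, p=10 problems.
- Monte-Carlo sizes: 500 replicates for effect recovery (MC standard error of
  the mean ≈ 0.035 on the soft-drinks coefficient), 1000 for the size of the
  test at α = 0.05, 100 seeds × n=200 for factor recovery (planted loading
  0.8, noise sd 0.6). The narrative driver `analysis/05_validation.py` uses
  trimmed counts (200/400/50) for a quick run; the acceptance checks use the
  full sizes.
- Seeds: every stochastic routine takes an explicit seed; replicate r of a
  harness uses seed + r.

## Limitations

- The shipped schema is a structural reconstruction; item wordings,
  item–area assignments and both weight vectors are editorial. Conclusions
  about specific policies should use a schema reflecting the actual
  instrument.
- With one observation per country the models are ecological; no causal
  claims, no multiple-testing correction (matching the original analysis
  plan), no uncertainty propagation from the index into the regression stage.
- Factor-score indeterminacy bounds how well any scoring method can track
  the latent factor; with seven indicators at loading 0.8 the theoretical
  score-factor correlation is ≈0.96, which is what the recovery simulation
  attains.
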