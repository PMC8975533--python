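# frei — the Food Regulatory Environment Index pipeline

`frei` builds a composite indicator of how comprehensively a country has
implemented recommended food-environment policies, and relates it to household
consumption of obesogenic foods and drinks across countries. It is aimed at
public-health researchers and policy analysts who want a transparent,
fully-tested implementation of the index's construction and of the ecological
association analysis around it — together with a synthetic-data generator so
every stage can be validated with known ground truth (the original survey
responses and sales data are proprietary).

## The method

**Index.** Binary policy responses x<sub>cj</sub> ∈ {0,1} (country *c*,
policy item *j*) are grouped into 15 sub-indicators (policy areas: national
strategies, coordination, school programmes, dietary guidelines, labelling,
nutrient declarations, front-of-pack and menu labelling, health-claims rules,
reformulation, trans-fat elimination, portion sizes, fiscal policies,
marketing restrictions, media campaigns). For sub-indicator *k* with weights
w<sub>j</sub>,

  S<sub>ck</sub> = Σ<sub>j∈k</sub> w<sub>j</sub> x<sub>cj</sub> / Σ<sub>j∈k</sub> w<sub>j</sub>,  raw<sub>c</sub> = (1/15) Σ<sub>k</sub> S<sub>ck</sub>

(linear aggregation: equal sub-indicator weights). Three formulations differ
only in w: **unweighted** (w ≡ 1), **aha** (integer 0–9 evidence grades from
recommendation class I–III × evidence level A–C), **informas** (Delphi-style
relative-importance weights). Raw scores are min-max rescaled to
1 + 99·(raw − min)/(max − min), so the benchmark country scores exactly 100;
countries are ranked descending with average ranks on ties.

**Diet composite.** Per-product household consumption (kg or L per household
per year, seven HFSS categories) is column-standardized to z-scores and one
common factor is extracted by principal-axis factoring; regression-method
factor scores form the Obesogenic Household Diet composite (sign fixed so
higher = more obesogenic).

**Association models.** For each outcome (product consumption, raw or
natural-log, or the composite), OLS of the outcome on the rescaled index,
either unadjusted or adjusted for European subregion (Central Eastern
reference), GDP annual growth, urban population % and female labour-force
participation %, with classical standard errors, t-based p-values and 95% CIs
on n ≈ 38 countries.

## Worked example

```
$ frei all --seed 1 --out run/
$ python analysis/01_simulate_study.py && python analysis/02_build_index.py \
    && python analysis/04_association_models.py
```

The drivers print, for the default synthetic study (38 countries × 60 items,
seed 1):

```
unweighted vs aha: Pearson(scores)=0.997, Spearman(ranks)=0.993
unweighted vs informas: Pearson(scores)=0.997, Spearman(ranks)=0.994
```

— evidence-weighting barely moves the rankings, exactly the behaviour the
index is known for — and the adjusted model coefficients, e.g.

```
soft_drinks   -3.689 (SE 0.601) 95% CI [-4.92; -2.46]  R²=0.734
```

meaning: in this one simulated study, each additional index point is
associated with ~3.7 fewer litres of soft drinks per household per year after
adjustment (the generator planted −2.148; a single study of 38 countries
scatters around the truth, and `analysis/05_validation.py` shows the
estimator is unbiased over replicates: mean −2.245 ± MC error over 200
replicates, 95% CI coverage 0.935, t-test size 0.052).

## Layout

- `src/frei/` — the library: `schema` (policy data model + I/O), `index`
  (formulations, rescaling, ranking), `composite` (z-scores + factor
  analysis), `models` (design matrices + OLS suite), `simulate` (synthetic
  studies), `validate` (Monte-Carlo harnesses), `report`, `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `docs/methods.md` — modelling assumptions, parameter choices, limitations.
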