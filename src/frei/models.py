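"""Cross-country association models: consumption and diet composite on FREI.

For each outcome (a product's household consumption, raw or log-transformed,
or the obesogenic-diet factor score) and each index formulation, an ordinary
least squares model is fitted, either unadjusted (intercept + FREI score) or
adjusted for European subregion (Central Eastern as reference), GDP annual
growth, urban population share and female labour-force participation.  This is
an ecological analysis: the unit is the country, n is small (tens), and
classical homoskedastic standard errors are reported, with HC3 robust errors
available behind a flag.  Countries missing any required variable are dropped
(complete-case analysis) and every drop is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .index import FreiScores

__all__ = [
    "SUBREGIONS",
    "REFERENCE_SUBREGION",
    "ModelSpec",
    "RegressionResult",
    "validate_covariates",
    "log_transform",
    "build_design",
    "fit_ols",
    "model_suite",
]

logger = logging.getLogger(__name__)

SUBREGIONS = (
    "Central Eastern",
    "Central Western",
    "Eastern",
    "Nordic",
    "South Eastern",
    "Southern",
    "Western",
)
REFERENCE_SUBREGION = "Central Eastern"


@dataclass(frozen=True)
class ModelSpec:
    """One model cell: outcome, transform, formulation, adjustment set."""

    outcome: str
    log_outcome: bool = False
    formulation: str = "unweighted"
    adjusted: bool = True
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError(f"ci_level must be in (0,1), got {self.ci_level}")


@dataclass
class RegressionResult:
    """Coefficient table plus fit statistics for one OLS model."""

    params: pd.DataFrame  # index = term; columns estimate, se, t, p, ci_lo, ci_hi
    n_obs: int
    r_squared: float
    df_resid: int
    spec: ModelSpec | None = None
    dropped_countries: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"R² out of [0,1]: {self.r_squared}")


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Check bounds and subregion levels of a country covariate table."""
    required = {"gdp_growth", "urban_pct", "female_lfp_pct", "subregion"}
    missing = required - set(cov.columns)
    if missing:
        raise ValueError(f"covariate table lacks column(s): {sorted(missing)}")
    for col in ("urban_pct", "female_lfp_pct"):
        vals = cov[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            bad = cov.index[(cov[col] < 0) | (cov[col] > 100)][0]
            raise ValueError(f"{col} out of [0,100] for country {bad!r}")
    bad_levels = set(cov["subregion"].dropna()) - set(SUBREGIONS)
    if bad_levels:
        raise ValueError(f"unknown subregion level(s): {sorted(bad_levels)}")
    return cov


def log_transform(values: pd.Series | pd.DataFrame):
    """Natural log, elementwise; refuses non-positive values (no offset)."""
    arr = values if isinstance(values, (pd.Series, pd.DataFrame)) else pd.Series(values)
    if isinstance(arr, pd.DataFrame):
        if (arr <= 0).any().any():
            col = arr.columns[(arr <= 0).any()][0]
            row = arr.index[arr[col] <= 0][0]
            raise ValueError(f"log transform of non-positive value at {row!r}/{col!r}")
    else:
        if (arr <= 0).any():
            row = arr.index[arr <= 0][0]
            raise ValueError(f"log transform of non-positive value at {row!r}")
    return np.log(arr)


def build_design(
    frei: FreiScores,
    cov: pd.DataFrame,
    outcome: pd.Series,
    spec: ModelSpec,
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Join outcome, index and covariates into (y, X, dropped countries).

    Adjusted models use intercept + FREI rescaled score + six subregion
    indicators (reference level omitted) + GDP growth + urban % + female LFP;
    unadjusted models use intercept + FREI only.  Rows are sorted by country
    id; countries missing any required field are dropped and reported.
    """
    df = pd.DataFrame({"frei": frei.rescaled, "y": outcome})
    if spec.adjusted:
        validate_covariates(cov)
        df = df.join(cov[["gdp_growth", "urban_pct", "female_lfp_pct", "subregion"]], how="outer")
    all_countries = sorted(df.index)
    kept = df.dropna()
    dropped = sorted(set(all_countries) - set(kept.index))
    if dropped:
        logger.info("complete-case join dropped countries: %s", dropped)
    kept = kept.sort_index()
    y = kept["y"]
    if spec.log_outcome:
        y = log_transform(y)
    X = pd.DataFrame({"const": 1.0, "frei": kept["frei"]}, index=kept.index)
    if spec.adjusted:
        for level in SUBREGIONS:
            if level == REFERENCE_SUBREGION:
                continue
            col = (kept["subregion"] == level).astype(float)
            if col.sum() == 0:
                logger.warning("subregion level %r absent; indicator dropped", level)
                continue
            X[f"subregion[{level}]"] = col
        X["gdp_growth"] = kept["gdp_growth"].astype(float)
        X["urban_pct"] = kept["urban_pct"].astype(float)
        X["female_lfp_pct"] = kept["female_lfp_pct"].astype(float)
    return y, X, dropped


def fit_ols(
    y: pd.Series,
    X: pd.DataFrame,
    ci_level: float = 0.95,
    robust: bool = False,
) -> RegressionResult:
    """Ordinary least squares with classical (or HC3) standard errors.

    Estimates satisfy the normal equations β = (XᵀX)⁻¹Xᵀy; p-values are
    two-sided from the t distribution on n − p degrees of freedom and the CI
    is estimate ± t·SE.
    """
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} observations but p={p} parameters: model unidentifiable")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # name the culprits: columns whose removal restores full rank
        collinear = []
        for col in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == rank:
                collinear.append(col)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")
    model = sm.OLS(np.asarray(y, dtype=float), X.astype(float))
    fit = model.fit(cov_type="HC3") if robust else model.fit()
    alpha = 1.0 - ci_level
    ci = fit.conf_int(alpha=alpha)
    params = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "ci_lo": ci[0],
            "ci_hi": ci[1],
        }
    )
    params.index.name = "term"
    return RegressionResult(
        params=params,
        n_obs=int(fit.nobs),
        r_squared=float(fit.rsquared),
        df_resid=int(fit.df_resid),
    )


def model_suite(
    frei_by_formulation: dict[str, FreiScores],
    consumption: pd.DataFrame,
    composite_scores: pd.Series,
    cov: pd.DataFrame,
    products: tuple[str, ...] | None = None,
    ci_level: float = 0.95,
    robust: bool = False,
) -> pd.DataFrame:
    """Fit every (outcome × transform × formulation × adjustment) model cell.

    Outcomes are each product's consumption on the raw and the log scale plus
    the diet composite (raw only).  Returns a tidy long table with one row per
    model term; failed cells are recorded with an ``error`` column and the
    suite continues.
    """
    if products is None:
        products = tuple(consumption.columns)
    outcomes: list[tuple[str, pd.Series, bool]] = []
    for prod in products:
        outcomes.append((prod, consumption[prod], False))
        outcomes.append((prod, consumption[prod], True))
    outcomes.append(("diet_composite", composite_scores, False))

    rows = []
    for outcome_name, outcome, logged in outcomes:
        for formulation, frei in frei_by_formulation.items():
            for adjusted in (False, True):
                spec = ModelSpec(
                    outcome=outcome_name,
                    log_outcome=logged,
                    formulation=formulation,
                    adjusted=adjusted,
                    ci_level=ci_level,
                )
                model_id = (
                    f"{outcome_name}|{'log' if logged else 'raw'}|{formulation}|"
                    f"{'adj' if adjusted else 'unadj'}"
                )
                try:
                    y, X, dropped = build_design(frei, cov, outcome, spec)
                    res = fit_ols(y, X, ci_level=ci_level, robust=robust)
                except Exception as exc:  # cell fails, suite continues
                    logger.warning("model %s failed: %s", model_id, exc)
                    rows.append(
                        {
                            "model_id": model_id,
                            "outcome": outcome_name,
                            "transform": "log" if logged else "raw",
                            "formulation": formulation,
                            "adjusted": adjusted,
                            "term": None,
                            "error": str(exc),
                        }
                    )
                    continue
                for term, r in res.params.iterrows():
                    rows.append(
                        {
                            "model_id": model_id,
                            "outcome": outcome_name,
                            "transform": "log" if logged else "raw",
                            "formulation": formulation,
                            "adjusted": adjusted,
                            "term": term,
                            "estimate": r["estimate"],
                            "se": r["se"],
                            "t": r["t"],
                            "p": r["p"],
                            "ci_lo": r["ci_lo"],
                            "ci_hi": r["ci_hi"],
                            "n": res.n_obs,
                            "r2": res.r_squared,
                            "error": "",
                        }
                    )
    return pd.DataFrame(rows)
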