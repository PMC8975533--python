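"""Obesogenic Household Diet composite.

Household consumption of HFSS product categories (sugar and chocolate
confectionery, biscuits, savoury snacks, soft drinks, sports/energy drinks and
carbonates; kg or litres per household per year) is condensed into one score
per country: each product column is standardized to a z-score and a single
common factor is extracted, whose regression-method score is the composite.
Higher scores mean a more obesogenic household diet; the factor's arbitrary
sign is fixed by requiring the mean loading to be positive.

Extraction is principal-axis factoring (iterated communalities, starting from
squared multiple correlations), the conventional choice for composite
indicators; a maximum-likelihood fit is available as an option.  Both are
implemented here on the correlation matrix with numpy/scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "PRODUCTS",
    "DRINK_PRODUCTS",
    "CORE_PRODUCTS",
    "DietComposite",
    "validate_consumption",
    "zscore",
    "fit_single_factor",
    "obesogenic_diet_index",
]

# Litres/household/year for drinks, kg/household/year for foods.
PRODUCTS = (
    "sugar_confectionery",
    "chocolate_confectionery",
    "biscuits",
    "savoury_snacks",
    "soft_drinks",
    "sports_energy_drinks",
    "carbonates",
)
DRINK_PRODUCTS = ("soft_drinks", "sports_energy_drinks", "carbonates")
# Narrower preset matching the composite's defining product list (drops
# sports/energy drinks and keeps one soft-drinks aggregate with carbonates).
CORE_PRODUCTS = (
    "sugar_confectionery",
    "chocolate_confectionery",
    "biscuits",
    "savoury_snacks",
    "soft_drinks",
    "carbonates",
)


@dataclass
class DietComposite:
    """Factor-analytic composite: z-scores, loadings, and per-country scores."""

    z: pd.DataFrame
    loadings: pd.Series
    scores: pd.Series
    communalities: pd.Series
    products: tuple[str, ...]
    method: str
    n_iter: int = 0
    provenance: dict = field(default_factory=dict)


def validate_consumption(table: pd.DataFrame, products=PRODUCTS) -> pd.DataFrame:
    """Check a country × product consumption table: complete, strictly positive."""
    missing = set(products) - set(table.columns)
    if missing:
        raise ValueError(f"consumption table lacks product column(s): {sorted(missing)}")
    out = table[list(products)].astype(float)
    if out.isna().any().any():
        col = out.columns[out.isna().any()][0]
        country = out.index[out[col].isna()][0]
        raise ValueError(f"missing consumption cell: country {country!r}, product {col!r}")
    if (out <= 0).any().any():
        col = out.columns[(out <= 0).any()][0]
        country = out.index[out[col] <= 0][0]
        raise ValueError(
            f"non-positive consumption at country {country!r}, product {col!r}: "
            f"{out.loc[country, col]!r}"
        )
    return out


def zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Columnwise (x - mean)/sd with the sample (n-1) standard deviation."""
    if len(table) < 3:
        raise ValueError("z-scoring needs at least 3 countries")
    sd = table.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValueError(f"product {bad!r} has zero variance; z-score undefined")
    return (table - table.mean()) / sd


def _paf(R: np.ndarray, max_iter: int, tol: float) -> tuple[np.ndarray, int]:
    """Principal-axis factoring, one factor; returns loadings and iterations."""
    p = R.shape[0]
    # initial communalities: squared multiple correlations
    try:
        Rinv = np.linalg.inv(R)
        h2 = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 1.0 - 1e-3)
    h2 = np.clip(h2, 1e-6, 1 - 1e-6)
    lam = np.zeros(p)
    for it in range(1, max_iter + 1):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        evals, evecs = np.linalg.eigh(Rr)
        k = np.argmax(evals)
        ev = max(evals[k], 0.0)
        lam = np.sqrt(ev) * evecs[:, k]
        new_h2 = np.clip(lam**2, 1e-6, 1 - 1e-6)
        if np.max(np.abs(new_h2 - h2)) < tol:
            return lam, it
        h2 = new_h2
    raise RuntimeError(
        f"principal-axis factoring did not converge in {max_iter} iterations "
        f"(last communality change {np.max(np.abs(new_h2 - h2)):.3e}, tol {tol:g})"
    )


def _ml_factor(R: np.ndarray) -> np.ndarray:
    """One-factor maximum-likelihood fit of a correlation matrix."""
    p = R.shape[0]

    def negll(psi_logit):
        psi = 1e-4 + (1 - 2e-4) / (1 + np.exp(-psi_logit))
        d = 1.0 / np.sqrt(psi)
        Rs = d[:, None] * R * d[None, :]
        evals = np.linalg.eigvalsh(Rs)[::-1]
        # profile likelihood discrepancy for the smallest p-1 eigenvalues
        rest = evals[1:]
        return float(np.sum(np.log(rest) - rest) * -1.0)

    x0 = np.zeros(p)
    res = optimize.minimize(negll, x0, method="L-BFGS-B")
    psi = 1e-4 + (1 - 2e-4) / (1 + np.exp(-res.x))
    d = 1.0 / np.sqrt(psi)
    Rs = d[:, None] * R * d[None, :]
    evals, evecs = np.linalg.eigh(Rs)
    k = np.argmax(evals)
    lam_star = np.sqrt(max(evals[k] - 1.0, 0.0)) * evecs[:, k]
    return lam_star / d


def fit_single_factor(
    z: pd.DataFrame,
    method: str = "paf",
    max_iter: int = 200,
    tol: float = 1e-6,
) -> DietComposite:
    """Extract one common factor from standardized data.

    Scores use the regression (Thurstone) method, F = Z R⁻¹ λ.  The sign is
    fixed so that the mean loading is positive.
    """
    Z = z.to_numpy(dtype=float)
    n, p = Z.shape
    R = np.corrcoef(Z, rowvar=False)
    if method == "paf":
        lam, it = _paf(R, max_iter=max_iter, tol=tol)
    elif method == "ml":
        lam, it = _ml_factor(R), 0
    else:
        raise ValueError(f"unknown extraction method {method!r}")
    if lam.mean() < 0:
        lam = -lam
    # pinv rather than solve: R is singular in degenerate (perfectly
    # correlated) cases, where the minimum-norm weights are still well defined
    weights = np.linalg.pinv(R, hermitian=True) @ lam
    scores = Z @ weights
    return DietComposite(
        z=z,
        loadings=pd.Series(lam, index=z.columns, name="loading"),
        scores=pd.Series(scores, index=z.index, name="factor_score"),
        communalities=pd.Series(lam**2, index=z.columns, name="communality"),
        products=tuple(z.columns),
        method=method,
        n_iter=it,
        provenance={"n": n, "p": p, "max_iter": max_iter, "tol": tol},
    )


def obesogenic_diet_index(
    table: pd.DataFrame,
    products=PRODUCTS,
    method: str = "paf",
) -> DietComposite:
    """Validate → z-score → single-factor composite, with provenance recorded."""
    vals = validate_consumption(table, products=products)
    comp = fit_single_factor(zscore(vals), method=method)
    comp.provenance["products"] = list(products)
    return comp
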