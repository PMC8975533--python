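"""Construction of the Food Regulatory Environment Index (FREI).

Three formulations are computed from the same binary response matrix:

* ``unweighted`` — every policy item counts equally;
* ``aha`` — items weighted by the 0–9 evidence grade (recommendation class ×
  level of evidence);
* ``informas`` — items weighted by Delphi-style relative-importance weights.

All formulations share a two-level architecture: within each of the 15
sub-indicators a (weighted) mean of the item scores is taken, then the
sub-indicator scores are aggregated linearly with equal weights into one raw
score in [0, 1].  Raw scores are rescaled onto a 1–100 scale where the
benchmark (best) country is anchored at exactly 100, and countries are ranked
(1 = most comprehensive policy set, average ranks on ties).

A flat single-level weighted mean over all items, and a
proportional-to-maximum rescaling, are available as options for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schema import PolicyResponses, PolicySchema

__all__ = [
    "FORMULATIONS",
    "SubIndicatorScores",
    "FreiScores",
    "sub_indicator_scores",
    "aggregate",
    "rescale_scores",
    "rank_countries",
    "compute_frei",
    "compare_formulations",
    "frei_table",
]

FORMULATIONS = ("unweighted", "aha", "informas")
MISSING_POLICIES = ("as_absent", "renormalize")


@dataclass
class SubIndicatorScores:
    """Country × sub-indicator matrix of scores in [0, 1]."""

    values: pd.DataFrame
    formulation: str

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise ValueError("sub-indicator scores must lie in [0, 1]")


@dataclass
class FreiScores:
    """Per-country raw score, rescaled 1–100 score and rank, one formulation."""

    raw: pd.Series
    rescaled: pd.Series
    ranks: pd.Series
    formulation: str

    @property
    def countries(self) -> list[str]:
        return list(self.raw.index)


def _resolve_missing(values: pd.DataFrame, missing_policy: str) -> pd.DataFrame:
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}; use one of {MISSING_POLICIES}")
    if missing_policy == "as_absent":
        return values.fillna(0.0)
    return values  # renormalize: NaN-aware weighted means downstream


def sub_indicator_scores(
    responses: PolicyResponses,
    schema: PolicySchema,
    formulation: str = "unweighted",
    missing_policy: str = "as_absent",
) -> SubIndicatorScores:
    """Weighted mean of item scores within each sub-indicator.

    The unweighted formulation is the arithmetic mean; weighted formulations
    compute sum(w_i x_i)/sum(w_i) over the sub-indicator's items.  Under the
    ``renormalize`` missing policy the mean runs over non-missing items only;
    under the default ``as_absent`` policy missing responses score 0.
    """
    if formulation not in FORMULATIONS:
        raise ValueError(f"unknown formulation {formulation!r}; use one of {FORMULATIONS}")
    w = schema.weights(formulation)
    vals = _resolve_missing(responses.values, missing_policy)
    cols = {}
    for sub in schema.sub_indicators:
        items = list(sub.items)
        wsub = w[items]
        if float(wsub.sum()) == 0.0:
            raise ValueError(
                f"sub-indicator {sub.sub_indicator_id!r} has total weight 0 under "
                f"formulation {formulation!r}: weighted mean undefined"
            )
        x = vals[items]
        if missing_policy == "renormalize":
            mask = x.notna().to_numpy(dtype=float)
            num = np.nansum(x.to_numpy(dtype=float) * wsub.to_numpy(), axis=1)
            den = mask @ wsub.to_numpy()
            if np.any(den == 0.0):
                bad = x.index[den == 0.0][0]
                raise ValueError(
                    f"country {bad!r} has no non-missing items in sub-indicator "
                    f"{sub.sub_indicator_id!r}; cannot renormalize"
                )
            cols[sub.sub_indicator_id] = num / den
        else:
            cols[sub.sub_indicator_id] = (x.to_numpy(dtype=float) @ wsub.to_numpy()) / float(
                wsub.sum()
            )
    out = pd.DataFrame(cols, index=vals.index)
    return SubIndicatorScores(values=out, formulation=formulation)


def flat_scores(
    responses: PolicyResponses,
    schema: PolicySchema,
    formulation: str = "unweighted",
    missing_policy: str = "as_absent",
) -> pd.Series:
    """Single-level alternative: one weighted mean over all items (sensitivity)."""
    w = schema.weights(formulation)
    vals = _resolve_missing(responses.values, missing_policy)[schema.item_ids]
    if missing_policy == "renormalize":
        mask = vals.notna().to_numpy(dtype=float)
        num = np.nansum(vals.to_numpy(dtype=float) * w.to_numpy(), axis=1)
        den = mask @ w.to_numpy()
        raw = num / den
    else:
        raw = vals.to_numpy(dtype=float) @ w.to_numpy() / float(w.sum())
    return pd.Series(raw, index=vals.index, name="raw_score")


def aggregate(sub_scores: SubIndicatorScores) -> pd.Series:
    """Linear aggregation: equal-weight arithmetic mean across sub-indicators."""
    if sub_scores.values.shape[1] == 0:
        raise ValueError("cannot aggregate an empty sub-indicator set")
    return sub_scores.values.mean(axis=1).rename("raw_score")


def rescale_scores(raw: pd.Series, mode: str = "minmax") -> pd.Series:
    """Map raw scores onto the 1–100 scale; the benchmark country gets 100.

    ``minmax`` (default) is the affine map 1 + 99*(raw - min)/(max - min);
    ``proportional`` maps raw/max onto 100 and leaves the lower anchor free.
    """
    if len(raw) < 2:
        raise ValueError("rescaling needs at least two countries")
    lo, hi = float(raw.min()), float(raw.max())
    if mode == "minmax":
        if hi == lo:
            raise ValueError("all raw scores identical: min-max rescaling undefined")
        out = 1.0 + 99.0 * (raw - lo) / (hi - lo)
    elif mode == "proportional":
        if hi == 0:
            raise ValueError("maximum raw score is 0: proportional rescaling undefined")
        out = 100.0 * raw / hi
    else:
        raise ValueError(f"unknown rescale mode {mode!r}")
    return out.rename("rescaled_score")


def rank_countries(rescaled: pd.Series) -> pd.Series:
    """Descending ranks (1 = benchmark); tied countries share the average rank."""
    return rescaled.rank(ascending=False, method="average").rename("rank")


def compute_frei(
    responses: PolicyResponses,
    schema: PolicySchema,
    formulation: str = "unweighted",
    missing_policy: str = "as_absent",
    rescale_mode: str = "minmax",
    weight_mode: str = "two_level",
) -> FreiScores:
    """Full pipeline: sub-indicator scores → aggregate → rescale → rank."""
    if weight_mode == "two_level":
        raw = aggregate(
            sub_indicator_scores(responses, schema, formulation, missing_policy)
        )
    elif weight_mode == "flat":
        raw = flat_scores(responses, schema, formulation, missing_policy)
    else:
        raise ValueError(f"unknown weight mode {weight_mode!r}")
    rescaled = rescale_scores(raw, mode=rescale_mode)
    return FreiScores(
        raw=raw,
        rescaled=rescaled,
        ranks=rank_countries(rescaled),
        formulation=formulation,
    )


def compare_formulations(a: FreiScores, b: FreiScores) -> dict[str, float]:
    """Pearson correlation of rescaled scores and Spearman correlation of ranks."""
    if set(a.countries) != set(b.countries):
        raise ValueError("formulations cover different country sets")
    if len(a.countries) < 3:
        raise ValueError("need at least 3 countries to correlate formulations")
    bb_scores = b.rescaled.reindex(a.rescaled.index)
    bb_ranks = b.ranks.reindex(a.ranks.index)
    pearson = float(stats.pearsonr(a.rescaled, bb_scores).statistic)
    spearman = float(stats.spearmanr(a.ranks, bb_ranks).statistic)
    return {"pearson_scores": pearson, "spearman_ranks": spearman}


def frei_table(scores: FreiScores) -> pd.DataFrame:
    """Tidy per-country table: country, formulation, raw, rescaled, rank."""
    out = pd.DataFrame(
        {
            "country": scores.raw.index,
            "formulation": scores.formulation,
            "raw_score": scores.raw.to_numpy(),
            "rescaled_score": scores.rescaled.to_numpy(),
            "rank": scores.ranks.to_numpy(),
        }
    )
    return out
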