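"""Index construction: weighted sub-indicator means, aggregation, rescaling, ranks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frei.index import (
    FORMULATIONS,
    aggregate,
    compare_formulations,
    compute_frei,
    rank_countries,
    rescale_scores,
    sub_indicator_scores,
)
from frei.schema import PolicyItem, PolicyResponses, PolicySchema, SubIndicator
from .conftest import make_responses, make_schema


def brute_force_scores(values, schema, weights_by_item):
    """Independent straight-line recomputation: loops, no pandas algebra."""
    raw = {}
    for country in values.index:
        sub_means = []
        for sub in schema.sub_indicators:
            num = den = 0.0
            for iid in sub.items:
                x = values.loc[country, iid]
                x = 0.0 if pd.isna(x) else float(x)
                w = weights_by_item[iid]
                num += w * x
                den += w
            sub_means.append(num / den)
        raw[country] = sum(sub_means) / len(sub_means)
    lo, hi = min(raw.values()), max(raw.values())
    rescaled = {c: 1 + 99 * (v - lo) / (hi - lo) for c, v in raw.items()}
    return raw, rescaled


def weights_dict(schema, formulation):
    if formulation == "unweighted":
        return {it.item_id: 1.0 for it in schema.items}
    if formulation == "aha":
        return {it.item_id: float(it.weight_aha) for it in schema.items}
    return {it.item_id: float(it.weight_informas) for it in schema.items}


def two_item_schema(w_informas=(2.0, 1.0)):
    items = (
        PolicyItem("i0", "a", "s0", 1, w_informas[0]),
        PolicyItem("i1", "b", "s0", 1, w_informas[1]),
    )
    subs = (SubIndicator("s0", "Area", ("i0", "i1")),)
    return PolicySchema(sub_indicators=subs, items=items, aha_grade_map={})


def responses_from(mat, schema, countries=None):
    countries = countries or [f"C{i}" for i in range(len(mat))]
    df = pd.DataFrame(np.asarray(mat, dtype=float), index=countries, columns=schema.item_ids)
    return PolicyResponses(values=df)


class TestSubIndicatorScores:
    def test_unweighted_mean(self):
        schema = make_schema(1, 3)
        resp = responses_from([[1, 0, 1]], schema)
        s = sub_indicator_scores(resp, schema, "unweighted")
        assert s.values.iloc[0, 0] == pytest.approx(2 / 3)

    def test_double_weight_halves_contribution(self):
        """Items (1,0) with weights (2,1) give weighted mean 2/3."""
        schema = two_item_schema()
        resp = responses_from([[1, 0], [1, 1]], schema)
        s = sub_indicator_scores(resp, schema, "informas")
        assert s.values.iloc[0, 0] == pytest.approx(2 / 3)

    def test_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(11)
        schema = make_schema(3, 4, rng)
        resp = make_responses(schema, 8, rng)
        s = sub_indicator_scores(resp, schema, "aha")
        w = weights_dict(schema, "aha")
        for country in resp.values.index:
            for sub in schema.sub_indicators:
                num = sum(w[i] * resp.values.loc[country, i] for i in sub.items)
                den = sum(w[i] for i in sub.items)
                assert s.values.loc[country, sub.sub_indicator_id] == pytest.approx(
                    num / den, abs=1e-12
                )

    def test_zero_total_weight_is_explicit_error(self):
        items = (PolicyItem("i0", "a", "s0", 0, 0.0),)
        schema = PolicySchema(
            sub_indicators=(SubIndicator("s0", "Area", ("i0",)),),
            items=items, aha_grade_map={},
        )
        resp = responses_from([[1], [0]], schema)
        with pytest.raises(ValueError, match="total weight 0"):
            sub_indicator_scores(resp, schema, "aha")

    def test_renormalize_missing_policy_uses_observed_items_only(self):
        schema = make_schema(1, 2)
        df = pd.DataFrame([[1.0, np.nan]], index=["C0"], columns=schema.item_ids)
        resp = PolicyResponses(values=df.copy())
        as_absent = sub_indicator_scores(resp, schema, missing_policy="as_absent")
        resp2 = PolicyResponses(values=df.copy())
        renorm = sub_indicator_scores(resp2, schema, missing_policy="renormalize")
        assert as_absent.values.iloc[0, 0] == pytest.approx(0.5)
        assert renorm.values.iloc[0, 0] == pytest.approx(1.0)


class TestAggregateAndRescale:
    def test_all_present_scores_one(self):
        schema = make_schema(15, 2)
        resp = responses_from([[1] * 30, [0] * 30], schema)
        raw = aggregate(sub_indicator_scores(resp, schema))
        assert raw.iloc[0] == pytest.approx(1.0)
        assert raw.iloc[1] == pytest.approx(0.0)

    def test_row_mean(self):
        rng = np.random.default_rng(3)
        schema = make_schema(5, 3)
        resp = make_responses(schema, 6, rng)
        sub = sub_indicator_scores(resp, schema)
        pd.testing.assert_series_equal(
            aggregate(sub), sub.values.mean(axis=1).rename("raw_score")
        )

    def test_affine_midpoint(self):
        raw = pd.Series([0.2, 0.2 + 0.8 / 2, 1.0], index=list("abc"))
        out = rescale_scores(raw)
        assert list(out.round(10)) == [1.0, 50.5, 100.0]

    def test_benchmark_and_floor_anchored_exactly(self):
        rng = np.random.default_rng(5)
        raw = pd.Series(rng.random(12), index=[f"C{i}" for i in range(12)])
        out = rescale_scores(raw)
        assert out.max() == 100.0 and out.min() == 1.0
        assert out.idxmax() == raw.idxmax()

    def test_order_preservation(self):
        rng = np.random.default_rng(9)
        raw = pd.Series(rng.random(20))
        rho = stats.spearmanr(raw, rescale_scores(raw)).statistic
        assert rho == pytest.approx(1.0)

    def test_degenerate_all_equal_raises(self):
        with pytest.raises(ValueError, match="identical"):
            rescale_scores(pd.Series([0.5, 0.5, 0.5]))

    def test_proportional_mode_anchors_only_the_top(self):
        raw = pd.Series([0.25, 0.5, 1.0])
        out = rescale_scores(raw, mode="proportional")
        assert list(out) == [25.0, 50.0, 100.0]


class TestComputeFrei:
    def test_extreme_countries(self):
        schema = make_schema(3, 2)
        resp = responses_from([[1] * 6, [0] * 6], schema, ["AAA", "BBB"])
        s = compute_frei(resp, schema)
        assert s.rescaled["AAA"] == 100.0 and s.rescaled["BBB"] == 1.0
        assert s.ranks["AAA"] == 1 and s.ranks["BBB"] == 2

    @pytest.mark.parametrize("formulation", ["aha", "informas"])
    def test_equal_weights_reduce_to_unweighted(self, formulation):
        rng = np.random.default_rng(21)
        schema = make_schema(4, 3)  # all weights equal (1, 1.0)
        resp = make_responses(schema, 9, rng)
        a = compute_frei(resp, schema, formulation)
        b = compute_frei(resp, schema, "unweighted")
        assert np.allclose(a.rescaled, b.rescaled, atol=1e-12)

    def test_single_flip_never_lowers_raw_score(self):
        """Exhaustively flip each absent policy to present on a 5×10 matrix."""
        rng = np.random.default_rng(13)
        schema = make_schema(2, 5, rng)
        resp = make_responses(schema, 5, rng)
        for formulation in FORMULATIONS:
            base = compute_frei(resp, schema, formulation).raw
            for ci, country in enumerate(resp.values.index):
                for item in resp.values.columns:
                    if resp.values.loc[country, item] == 1.0:
                        continue
                    flipped = resp.values.copy()
                    flipped.loc[country, item] = 1.0
                    new = compute_frei(
                        PolicyResponses(values=flipped), schema, formulation
                    ).raw
                    assert new[country] >= base[country] - 1e-13

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(17)
        schema = make_schema(3, 4, rng)
        resp = make_responses(schema, 8, rng)
        perm = rng.permutation(resp.values.index)
        resp_p = PolicyResponses(values=resp.values.loc[perm])
        a = compute_frei(resp, schema, "informas")
        b = compute_frei(resp_p, schema, "informas")
        pd.testing.assert_series_equal(a.rescaled.loc[perm], b.rescaled)


class TestRanksAndComparison:
    def test_descending_ranks(self):
        r = rank_countries(pd.Series([100.0, 50.0, 1.0]))
        assert list(r) == [1.0, 2.0, 3.0]

    def test_ties_share_average_rank(self):
        r = rank_countries(pd.Series([100.0, 70.0, 70.0, 1.0]))
        assert list(r) == [1.0, 2.5, 2.5, 4.0]

    def test_ranks_agree_with_sort_oracle(self):
        rng = np.random.default_rng(23)
        scores = pd.Series(rng.random(15))
        r = rank_countries(scores)
        order = scores.sort_values(ascending=False).index
        for pos, idx in enumerate(order, start=1):
            assert r[idx] == pos

    def test_self_comparison_is_unity(self):
        rng = np.random.default_rng(29)
        schema = make_schema(3, 3, rng)
        resp = make_responses(schema, 6, rng)
        s = compute_frei(resp, schema)
        out = compare_formulations(s, s)
        assert out == {"pearson_scores": pytest.approx(1.0), "spearman_ranks": pytest.approx(1.0)}

    def test_correlations_match_closed_form(self):
        rng = np.random.default_rng(31)
        schema = make_schema(3, 4, rng)
        resp = make_responses(schema, 10, rng)
        a = compute_frei(resp, schema, "unweighted")
        b = compute_frei(resp, schema, "aha")
        out = compare_formulations(a, b)
        x, y = a.rescaled.to_numpy(), b.rescaled.reindex(a.rescaled.index).to_numpy()
        pearson = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out["pearson_scores"] == pytest.approx(pearson, abs=1e-12)
        ra = rank_countries(a.rescaled).to_numpy()
        rb = rank_countries(b.rescaled.reindex(a.rescaled.index)).to_numpy()
        spearman = np.corrcoef(ra, rb)[0, 1]
        assert out["spearman_ranks"] == pytest.approx(spearman, abs=1e-12)

    def test_too_few_countries_rejected(self):
        schema = make_schema(2, 2)
        resp = responses_from([[1, 1, 1, 0], [0, 1, 0, 0]], schema)
        s = compute_frei(resp, schema)
        with pytest.raises(ValueError, match="3 countries"):
            compare_formulations(s, s)
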