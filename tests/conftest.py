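import numpy as np
import pandas as pd
import pytest

from frei.schema import (
    PolicyItem,
    PolicyResponses,
    PolicySchema,
    SubIndicator,
    load_default_schema,
)


@pytest.fixture(scope="session")
def default_schema():
    return load_default_schema()


def make_schema(n_subs: int, items_per_sub: int, rng: np.random.Generator | None = None):
    """Programmatic schema: n_subs sub-indicators × items_per_sub items.

    AHA weights are random integers 0–9 (at least one positive per
    sub-indicator so weighted means are defined); informas weights random
    positive reals.  With rng=None all weights are 1.
    """
    subs, items = [], []
    for s in range(n_subs):
        sid = f"sub{s}"
        iids = [f"s{s}_i{i}" for i in range(items_per_sub)]
        subs.append(SubIndicator(sub_indicator_id=sid, name=f"Area {s}", items=tuple(iids)))
        for iid in iids:
            if rng is None:
                wa, wi = 1, 1.0
            else:
                wa = int(rng.integers(0, 10))
                wi = float(rng.uniform(0.1, 2.5))
            items.append(
                PolicyItem(item_id=iid, label=iid, sub_indicator_id=sid,
                           weight_aha=wa, weight_informas=wi)
            )
        # guarantee nonzero total aha weight within the sub-indicator
        if rng is not None and sum(it.weight_aha for it in items[-items_per_sub:]) == 0:
            items[-1] = PolicyItem(item_id=items[-1].item_id, label=items[-1].label,
                                   sub_indicator_id=sid, weight_aha=1,
                                   weight_informas=items[-1].weight_informas)
    grade_map = {("I", "A"): 9, ("III", "C"): 0}
    return PolicySchema(sub_indicators=tuple(subs), items=tuple(items), aha_grade_map=grade_map)


def make_responses(schema: PolicySchema, n_countries: int, rng: np.random.Generator,
                   missing_rate: float = 0.0) -> PolicyResponses:
    vals = rng.integers(0, 2, size=(n_countries, len(schema.items))).astype(float)
    if missing_rate > 0:
        vals[rng.random(vals.shape) < missing_rate] = np.nan
    countries = [f"C{i:02d}" for i in range(n_countries)]
    df = pd.DataFrame(vals, index=pd.Index(countries, name="country"),
                      columns=schema.item_ids)
    return PolicyResponses(values=df)


@pytest.fixture
def toy_schema():
    return make_schema(2, 3)
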