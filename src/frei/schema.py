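"""Policy data model: schema, evidence-based weights, and binary responses.

The index is built from a country survey in which each question asks whether a
national food-environment policy is in place.  Responses are binary — a policy
is either present (1) or absent (0) — and questions are grouped into
sub-indicators corresponding to the recommended policy areas of the WHO
European Food and Nutrition Action Plan (15 areas, from national strategies and
coordination mechanisms through labelling, reformulation, fiscal policies and
marketing restrictions to media campaigns).

Two weight sets accompany every policy item:

* ``weight_aha`` — an integer 0–9 derived from the American Heart Association
  evidence grading, where (Class I, Level A) maps to 9 and (Class III, Level C)
  to 0;
* ``weight_informas`` — a non-negative real weight in the style of the
  INFORMAS/Food-EPI Delphi exercise (e.g. a high tax on unhealthy foods
  receives twice the weight of private workplace food policies).

The shipped default schema is a synthetic reconstruction of the survey
instrument's structure (the 15 named areas with plausible items and weights);
it is not a copy of the original questionnaire, whose item-level content is
not public.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PolicyItem",
    "SubIndicator",
    "PolicySchema",
    "PolicyResponses",
    "SchemaError",
    "ResponseError",
    "load_schema",
    "load_default_schema",
    "load_responses",
    "write_responses",
    "grade_to_weight",
    "AHA_CLASSES",
    "AHA_LEVELS",
]

AHA_CLASSES = ("I", "IIa", "IIb", "III")
AHA_LEVELS = ("A", "B", "C")


class SchemaError(ValueError):
    """Raised when a policy schema violates its invariants."""


class ResponseError(ValueError):
    """Raised when a response table violates the binary-coding contract."""


@dataclass(frozen=True)
class PolicyItem:
    """One binary survey question about the presence of a policy."""

    item_id: str
    label: str
    sub_indicator_id: str
    weight_aha: int
    weight_informas: float

    def __post_init__(self) -> None:
        if not (isinstance(self.weight_aha, (int, np.integer)) and 0 <= self.weight_aha <= 9):
            raise SchemaError(
                f"item {self.item_id!r}: weight_aha must be an integer in 0..9, "
                f"got {self.weight_aha!r}"
            )
        if self.weight_informas < 0:
            raise SchemaError(
                f"item {self.item_id!r}: weight_informas must be >= 0, "
                f"got {self.weight_informas!r}"
            )


@dataclass(frozen=True)
class SubIndicator:
    """A recommended policy area; its score is a (weighted) mean over items."""

    sub_indicator_id: str
    name: str
    items: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.items) == 0:
            raise SchemaError(f"sub-indicator {self.sub_indicator_id!r} has no items")


@dataclass(frozen=True)
class PolicySchema:
    """The full instrument: sub-indicators, items, and the AHA grade map."""

    sub_indicators: tuple[SubIndicator, ...]
    items: tuple[PolicyItem, ...]
    aha_grade_map: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for it in self.items:
            if it.item_id in seen:
                raise SchemaError(f"duplicate item_id {it.item_id!r}")
            seen.add(it.item_id)
        sub_ids = {s.sub_indicator_id for s in self.sub_indicators}
        if len(sub_ids) != len(self.sub_indicators):
            raise SchemaError("duplicate sub_indicator_id in schema")
        for it in self.items:
            if it.sub_indicator_id not in sub_ids:
                raise SchemaError(
                    f"item {it.item_id!r} references unknown sub-indicator "
                    f"{it.sub_indicator_id!r}"
                )
        # every item belongs to exactly one sub-indicator, and membership lists
        # agree with the item declarations
        owner: dict[str, str] = {}
        for sub in self.sub_indicators:
            for iid in sub.items:
                if iid in owner:
                    raise SchemaError(
                        f"item {iid!r} listed under both {owner[iid]!r} "
                        f"and {sub.sub_indicator_id!r}"
                    )
                owner[iid] = sub.sub_indicator_id
        for it in self.items:
            if owner.get(it.item_id) != it.sub_indicator_id:
                raise SchemaError(
                    f"item {it.item_id!r} declares sub-indicator "
                    f"{it.sub_indicator_id!r} but membership lists disagree"
                )
        if set(owner) != seen:
            missing = set(owner) - seen
            raise SchemaError(f"sub-indicator membership names unknown items: {sorted(missing)}")
        for (cls, level), w in self.aha_grade_map.items():
            if cls not in AHA_CLASSES or level not in AHA_LEVELS:
                raise SchemaError(f"aha_grade_map has unknown pair ({cls!r}, {level!r})")
            if not 0 <= int(w) <= 9:
                raise SchemaError(f"aha_grade_map[{cls!r},{level!r}] = {w!r} outside 0..9")

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def items_of(self, sub_indicator_id: str) -> list[PolicyItem]:
        by_id = {it.item_id: it for it in self.items}
        sub = next(
            s for s in self.sub_indicators if s.sub_indicator_id == sub_indicator_id
        )
        return [by_id[i] for i in sub.items]

    def weights(self, formulation: str) -> pd.Series:
        """Per-item weight vector for a formulation tag."""
        if formulation == "unweighted":
            w = [1.0] * len(self.items)
        elif formulation == "aha":
            w = [float(it.weight_aha) for it in self.items]
        elif formulation == "informas":
            w = [float(it.weight_informas) for it in self.items]
        else:
            raise ValueError(f"unknown formulation {formulation!r}")
        return pd.Series(w, index=self.item_ids, name=formulation)


@dataclass
class PolicyResponses:
    """Country × item binary matrix with explicit missingness.

    ``values`` is a float DataFrame indexed by country id with one column per
    schema item; cells are 0.0, 1.0 or NaN (missing).  ``missing_report``
    counts missing cells per country.
    """

    values: pd.DataFrame
    missing_report: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ResponseError(
                f"non-binary cell at country {self.values.index[i]!r}, "
                f"item {self.values.columns[j]!r}: {vals[i, j]!r}"
            )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ResponseError(f"duplicated country identifier {dup!r}")
        if self.missing_report is None:
            self.missing_report = self.values.isna().sum(axis=1)

    @property
    def countries(self) -> list[str]:
        return list(self.values.index)


def _build_schema(doc: dict) -> PolicySchema:
    subs = tuple(
        SubIndicator(
            sub_indicator_id=s["sub_indicator_id"],
            name=s["name"],
            items=tuple(s["items"]),
        )
        for s in doc["sub_indicators"]
    )
    items = tuple(
        PolicyItem(
            item_id=i["item_id"],
            label=i.get("label", i["item_id"]),
            sub_indicator_id=i["sub_indicator_id"],
            weight_aha=int(i["weight_aha"]),
            weight_informas=float(i["weight_informas"]),
        )
        for i in doc["items"]
    )
    grade_map = {
        (str(k["class"]), str(k["level"])): int(k["weight"])
        for k in doc.get("aha_grade_map", [])
    }
    return PolicySchema(sub_indicators=subs, items=items, aha_grade_map=grade_map)


def load_schema(source) -> PolicySchema:
    """Load and validate a policy schema from YAML (path, file object or str).

    Raises :class:`SchemaError` naming the offending entity before any
    computation if an invariant is violated.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" in text or text.lstrip().startswith("{"):
            doc = yaml.safe_load(io.StringIO(text))
        else:
            with open(text, "r", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
    return _build_schema(doc)


def load_default_schema() -> PolicySchema:
    """The shipped 15-area default schema (synthetic reconstruction)."""
    text = resources.files("frei").joinpath("data/default_schema.yaml").read_text("utf-8")
    return load_schema(io.StringIO(text))


def grade_to_weight(cls: str, level: str, grade_map: Mapping[tuple[str, str], int]) -> int:
    """Map an AHA (recommendation class, evidence level) pair to a 0–9 weight.

    An unmapped pair is an explicit error — there is no silent default.
    """
    key = (cls, level)
    if key not in grade_map:
        raise KeyError(f"AHA pair (class={cls!r}, level={level!r}) is not in the grade map")
    return int(grade_map[key])


def load_responses(table, schema: PolicySchema, country_col: str | None = None) -> PolicyResponses:
    """Read a country × item response table from delimited text.

    First column (or ``country_col``) holds the country identifier; remaining
    columns must exactly match the schema's item ids.  Cells are coerced to
    {0, 1, missing}; anything else raises :class:`ResponseError` naming the
    row and column.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, dtype=str, keep_default_na=False)
    if country_col is None:
        country_col = df.columns[0]
    df = df.set_index(country_col)
    unknown = set(df.columns) - set(schema.item_ids)
    if unknown:
        raise ResponseError(f"unknown response column(s): {sorted(unknown)}")
    missing_cols = set(schema.item_ids) - set(df.columns)
    if missing_cols:
        raise ResponseError(f"response table lacks item column(s): {sorted(missing_cols)}")
    df = df[schema.item_ids]

    def _coerce(cell, country, item):
        if isinstance(cell, float) and np.isnan(cell):
            return np.nan
        s = str(cell).strip()
        if s == "" or s.lower() in {"na", "nan"}:
            return np.nan
        if s in {"0", "0.0"}:
            return 0.0
        if s in {"1", "1.0"}:
            return 1.0
        raise ResponseError(
            f"cell value {cell!r} at country {country!r}, item {item!r} "
            "is outside {0, 1, empty}"
        )

    out = pd.DataFrame(
        [
            [_coerce(df.iat[i, j], df.index[i], df.columns[j]) for j in range(df.shape[1])]
            for i in range(df.shape[0])
        ],
        index=df.index,
        columns=df.columns,
        dtype=float,
    )
    return PolicyResponses(values=out)


def write_responses(responses: PolicyResponses, path) -> None:
    """Write responses as delimited text; missing cells become empty fields."""
    out = responses.values.copy()
    out.index.name = out.index.name or "country"
    # integers where present, empty where missing
    txt = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    txt.to_csv(path)


def write_schema(schema: PolicySchema, path) -> None:
    """Serialize a schema back to YAML (inverse of :func:`load_schema`)."""
    doc = {
        "sub_indicators": [
            {"sub_indicator_id": s.sub_indicator_id, "name": s.name, "items": list(s.items)}
            for s in schema.sub_indicators
        ],
        "items": [
            {
                "item_id": i.item_id,
                "label": i.label,
                "sub_indicator_id": i.sub_indicator_id,
                "weight_aha": int(i.weight_aha),
                "weight_informas": float(i.weight_informas),
            }
            for i in schema.items
        ],
        "aha_grade_map": [
            {"class": c, "level": l, "weight": int(w)}
            for (c, l), w in schema.aha_grade_map.items()
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
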