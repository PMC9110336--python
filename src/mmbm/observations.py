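"""Ingestion and recoding of behavioural-observation data.

Raw site-specific activity codes are mapped onto the five comparative
categories (childcare, food production, domestic work, play, other).  Coding
schemes at some sites allow an observation to fall into two categories at
once; such dual-coded observations are expanded into two records, each
counted as a unique observation.

Expected CSV schemas
--------------------
``observations.csv``: society_id, child_id, obs_index, raw_code
``children.csv``:     child_id, society_id, gender, age_years (blank allowed),
                      age_label (blank allowed)
``code_map.csv``:     raw_code, categories ("play|food_production" pipe-joined
                      for dual codes)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CATEGORIES

logger = logging.getLogger(__name__)

GENDERS = ("girl", "boy")
AGE_CLASSES = ("early", "middle", "adolescent")

#: numeric age bounds (whole years, inclusive) per developmental class
AGE_CLASS_BOUNDS = {"early": (3, 6), "middle": (7, 12), "adolescent": (13, 18)}

#: label path used where exact ages are unknown (Mikea-style age grades)
MIKEA_LABELS = {
    "early_juvenile": "early",
    "late_juvenile": "middle",
    "young_adult": "adolescent",
}

#: midpoint ages imputed for labelled children, for descriptive statistics only
MIKEA_MIDPOINT_AGE = {"early": 6.5, "middle": 12.0, "adolescent": 20.5}


class IngestionError(ValueError):
    """Raised when input observation data violate the ingestion contract."""


@dataclass(frozen=True)
class ObservationRecord:
    """One coded behavioural observation of one child."""

    society_id: str
    child_id: str
    obs_index: int
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise IngestionError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class ChildProfile:
    """Individual-level covariate carrier (gender, age class)."""

    child_id: str
    society_id: str
    gender: str
    age_class: str
    age_years: float | None = None

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise IngestionError(f"gender must be one of {GENDERS}")
        if self.age_class not in AGE_CLASSES:
            raise IngestionError(f"age_class must be one of {AGE_CLASSES}")
        if self.age_years is not None and self.age_years >= 3:
            lo, hi = AGE_CLASS_BOUNDS[self.age_class]
            if not (lo <= math.floor(self.age_years) <= hi) and self.age_years <= 18:
                raise IngestionError(
                    f"age_years {self.age_years} inconsistent with class "
                    f"{self.age_class!r}"
                )


class ActivityCodeMap:
    """Mapping from raw site codes to one or two comparative categories."""

    def __init__(self, entries: dict[str, tuple[str, ...]]):
        for code, cats in entries.items():
            if not (1 <= len(cats) <= 2):
                raise IngestionError(
                    f"code {code!r} maps to {len(cats)} categories; must be 1 or 2"
                )
            bad = [c for c in cats if c not in CATEGORIES]
            if bad:
                raise IngestionError(f"code {code!r} maps to unknown categories {bad}")
        self.entries = {k: tuple(v) for k, v in entries.items()}

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __getitem__(self, code: str) -> tuple[str, ...]:
        return self.entries[code]

    @classmethod
    def identity(cls) -> "ActivityCodeMap":
        """Trivial map where codes are already category names (or pairs
        joined by '+'), as produced by the synthetic generator."""
        entries = {c: (c,) for c in CATEGORIES}
        for a in CATEGORIES:
            for b in CATEGORIES:
                if a < b:
                    entries[f"{a}+{b}"] = (a, b)
        return cls(entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ActivityCodeMap":
        df = pd.read_csv(path, dtype=str)
        entries = {
            str(row.raw_code): tuple(str(row.categories).split("|"))
            for row in df.itertuples()
        }
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "raw_code": list(self.entries),
                "categories": ["|".join(v) for v in self.entries.values()],
            }
        ).to_csv(path, index=False)


def recode_observation(
    raw_code: str, code_map: ActivityCodeMap, society_id: str | None = None
) -> list[str]:
    """Map one raw activity code to its 1 or 2 comparative categories."""
    if raw_code not in code_map:
        where = f" in society {society_id!r}" if society_id else ""
        raise IngestionError(f"unknown raw activity code {raw_code!r}{where}")
    return list(code_map[raw_code])


def expand_observations(
    raw: pd.DataFrame, code_map: ActivityCodeMap
) -> pd.DataFrame:
    """Recode a raw observation table into five-category records.

    Dual-coded observations contribute two rows with equal weight (each
    counted as a unique observation); the returned frame therefore has
    ``len(raw) + n_dual`` rows.
    """
    required = {"society_id", "child_id", "obs_index", "raw_code"}
    missing = required - set(raw.columns)
    if missing:
        raise IngestionError(f"observations table missing columns {sorted(missing)}")
    rows: list[tuple] = []
    for row in raw.itertuples():
        cats = recode_observation(str(row.raw_code), code_map, str(row.society_id))
        for cat in cats:
            rows.append((row.society_id, row.child_id, row.obs_index, cat))
    return pd.DataFrame(
        rows, columns=["society_id", "child_id", "obs_index", "category"]
    )


def assign_age_class(
    age_years: float | None = None,
    mikea_label: str | None = None,
    allow_out_of_range: bool = False,
) -> str:
    """Developmental age class from a numeric age or a Mikea-style label.

    Numeric ages are floored to whole years before classification (the class
    bounds are stated in whole years): 3-6 early, 7-12 middle, 13-18
    adolescent.  Labelled children map early_juvenile->early,
    late_juvenile->middle, young_adult->adolescent; young adults up to age 25
    are admitted only via the label path.
    """
    if (age_years is None) == (mikea_label is None):
        raise ValueError("provide exactly one of age_years or mikea_label")
    if mikea_label is not None:
        if mikea_label not in MIKEA_LABELS:
            raise ValueError(f"unknown age label {mikea_label!r}")
        return MIKEA_LABELS[mikea_label]
    years = math.floor(age_years)
    if not allow_out_of_range and not (3 <= years <= 18):
        raise ValueError(
            f"age_years {age_years} outside the numeric range 3-18; "
            "use the label path or allow_out_of_range=True"
        )
    for cls, (lo, hi) in AGE_CLASS_BOUNDS.items():
        if lo <= years <= hi:
            return cls
    return "early" if years < 3 else "adolescent"


def load_children(path: str | Path) -> pd.DataFrame:
    """Read a child roster CSV and derive age classes.

    Children observed in multiple years should appear once, with
    ``age_years`` the mean age across years.
    """
    df = pd.read_csv(path, dtype={"child_id": str, "society_id": str})
    classes = []
    imputed_age = []
    for row in df.itertuples():
        age = getattr(row, "age_years", None)
        label = getattr(row, "age_label", None)
        has_age = age is not None and not pd.isna(age)
        has_label = isinstance(label, str) and label != ""
        if has_label:
            cls = assign_age_class(mikea_label=label)
            classes.append(cls)
            imputed_age.append(MIKEA_MIDPOINT_AGE[cls])
        elif has_age:
            classes.append(assign_age_class(age_years=float(age)))
            imputed_age.append(float(age))
        else:
            raise IngestionError(
                f"child {row.child_id}: neither age_years nor age_label given"
            )
    df = df.copy()
    df["age_class"] = classes
    df["age_for_description"] = imputed_age
    return df


def child_proportions(records: pd.DataFrame, children: pd.DataFrame) -> pd.DataFrame:
    """Per-child proportion of records in each category (rows sum to 1)."""
    unknown = set(records["child_id"]) - set(children["child_id"])
    if unknown:
        raise IngestionError(
            f"records reference unknown children: {sorted(unknown)[:5]}"
        )
    counts = (
        records.groupby(["child_id", "category"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    zero = set(children["child_id"]) - set(counts.index)
    if zero:
        logger.warning(
            "%d children have no observation records and are excluded", len(zero)
        )
    props = counts.div(counts.sum(axis=1), axis=0)
    props["n_obs"] = counts.sum(axis=1)
    return props.reset_index()


def summarize_time_allocation(
    records: pd.DataFrame,
    children: pd.DataFrame,
    grouping: tuple[str, ...] = ("society_id", "gender", "age_class"),
) -> pd.DataFrame:
    """Mean individual proportion of observed time per category, by group.

    Group values are unweighted means over children (each child contributes
    equally regardless of how often they were observed).  Also reports the
    observations-per-child mean and SD within each group.
    """
    props = child_proportions(records, children)
    merged = props.merge(
        children[["child_id", "society_id", "gender", "age_class"]],
        on="child_id",
        how="left",
    )
    group_cols = list(grouping)
    agg = merged.groupby(group_cols, observed=True).agg(
        **{f"mean_{c}": (c, "mean") for c in CATEGORIES},
        n_children=("child_id", "size"),
        mean_obs_per_child=("n_obs", "mean"),
        sd_obs_per_child=("n_obs", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
    )
    return agg.reset_index()


def time_allocation_long(
    records: pd.DataFrame,
    children: pd.DataFrame,
    grouping: tuple[str, ...] = ("society_id", "gender", "age_class"),
) -> pd.DataFrame:
    """Long-format mean individual proportions: one row per group x category."""
    wide = summarize_time_allocation(records, children, grouping)
    long = wide.melt(
        id_vars=list(grouping),
        value_vars=[f"mean_{c}" for c in CATEGORIES],
        var_name="category",
        value_name="mean_proportion",
    )
    long["category"] = long["category"].str.removeprefix("mean_")
    return long
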