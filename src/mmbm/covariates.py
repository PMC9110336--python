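"""Society-level socioecological covariates.

Builds the predictors used by the candidate models from ethnographer and
climate inputs:

* dietary composition -> proportion of non-foraged food,
* dietary composition x gendered division-of-labour scores -> the gendered
  division of food production labour statistic in [-2, 2],
* monthly climate series -> annual mean temperature (BIO1) and annual
  precipitation (BIO12) over a 30-year climatological window,
* curated dangerous-mammal densities -> a low/high class,
* a 4-point water quality/quantity rating (treated as numeric),
* z-score standardization across societies.

Expected CSV schemas
--------------------
``diet.csv``:            society_id, source, min_pct, max_pct, mean_pct,
                         division_score
``mammals.csv``:         society_id, species, density_n_per_km2
``climate_monthly.csv``: society_id, year, month, tmax_c, tmin_c, precip_mm
``society_static.csv``:  society_id, npp_gc_m2_yr, water_rating
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIET_SOURCES = (
    "wild_plants",
    "large_game",
    "small_game",
    "fish_seafood",
    "insects",
    "honey",
    "domesticated",
    "traded_purchased",
)

NON_FORAGED_SOURCES = ("domesticated", "traded_purchased")

WATER_RATINGS = (1, 2, 3, 4)  # 1 = enough good water ... 4 = scarce poor water

#: society-level columns that enter models on the z-scored scale
ZSCORED_COLUMNS = ("prop_non_foraged", "npp", "annual_mean_temp", "annual_precip")

DEFAULT_CLIMATE_WINDOW_YEARS = 30


class CovariateError(ValueError):
    """Raised when covariate inputs violate their contracts."""


class AmbiguousDensityError(CovariateError):
    """Total dangerous-mammal density falls in the unobserved middle band
    [1, 10] n/km^2, where no principled low/high split exists; an explicit
    manual class is required."""


@dataclass(frozen=True)
class DietarySourceEstimate:
    """Ethnographer estimate of one food source's dietary share and of which
    gender produces it (1 = women only ... 5 = men only)."""

    source: str
    division_score: float
    mean_pct: float | None = None
    min_pct: float | None = None
    max_pct: float | None = None

    def __post_init__(self) -> None:
        has_mean = self.mean_pct is not None
        has_range = self.min_pct is not None and self.max_pct is not None
        if has_mean == has_range:
            raise CovariateError(
                f"{self.source}: provide either mean_pct or (min_pct, max_pct)"
            )
        if not (1.0 <= self.division_score <= 5.0):
            raise CovariateError(
                f"{self.source}: division_score {self.division_score} outside [1, 5]"
            )

    @property
    def intake(self) -> float:
        """Point dietary intake: the mean, or the midpoint of (min, max)."""
        if self.mean_pct is not None:
            return float(self.mean_pct)
        return 0.5 * (float(self.min_pct) + float(self.max_pct))


def normalize_diet(estimates: list[DietarySourceEstimate]) -> dict[str, float]:
    """Per-source dietary proportions summing to 1.

    Min/max pairs collapse to their midpoint before normalization.
    """
    if not estimates:
        raise CovariateError("no dietary source estimates given")
    raw = {e.source: e.intake for e in estimates}
    if any(v < 0 for v in raw.values()):
        raise CovariateError("negative dietary intake")
    total = sum(raw.values())
    if total <= 0:
        raise CovariateError("all dietary intakes are zero")
    return {s: v / total for s, v in raw.items()}


def prop_non_foraged(proportions: dict[str, float]) -> float:
    """Proportion of the diet that is domesticated or purchased/traded."""
    return float(sum(proportions.get(s, 0.0) for s in NON_FORAGED_SOURCES))


def gendered_division(
    proportions: dict[str, float], division_scores: dict[str, float]
) -> float:
    """Gendered division of food production labour in [-2, 2].

    The intake-weighted mean of the 1-5 division scores, shifted by 3 so
    that -2 means women do all food production labour, +2 means men do, and
    0 means both genders contribute equally.
    """
    for s, d in division_scores.items():
        if not (1.0 <= d <= 5.0):
            raise CovariateError(f"division score {d} for {s!r} outside [1, 5]")
    value = sum(p * division_scores[s] for s, p in proportions.items())
    return float(value - 3.0)


def classify_mammal_density(species_densities: list[float]) -> tuple[str, float]:
    """Binarize the summed density of dangerous mammals.

    Returns (class, total): total < 1 n/km^2 -> "low"; total > 10 -> "high".
    The published site totals split naturally around those values; a total in
    [1, 10] has no principled class and raises
    :class:`AmbiguousDensityError` so the analyst must choose explicitly.
    """
    densities = [float(d) for d in species_densities]
    if any(d < 0 for d in densities):
        raise CovariateError("negative species density")
    total = float(sum(densities))
    if not densities:
        logger.warning("empty dangerous-mammal list; total density 0 -> low")
        return "low", 0.0
    if total < 1.0:
        return "low", total
    if total > 10.0:
        return "high", total
    raise AmbiguousDensityError(
        f"total dangerous-mammal density {total} n/km^2 lies in [1, 10]; "
        "assign the low/high class manually"
    )


def _climatological_months(series: pd.DataFrame, value: str) -> np.ndarray:
    """Mean of ``value`` per calendar month over the window years."""
    have = series.groupby("month")[value].count()
    years = series["year"].nunique()
    gaps = [
        m for m in range(1, 13) if have.get(m, 0) != years
    ] + ([] if set(series["month"]) <= set(range(1, 13)) else ["bad month values"])
    if len(series) != years * 12 or gaps:
        raise CovariateError(
            f"incomplete monthly climate series (expected {years} years x 12 "
            f"months); problems at months {gaps or 'row count'}"
        )
    return series.groupby("month")[value].mean().sort_index().to_numpy()


def bioclim_annual_mean_temp(series: pd.DataFrame) -> float:
    """Annual mean temperature (BIO1, degC) from a monthly tmax/tmin series.

    Monthly values are first averaged across the window years; BIO1 is the
    mean over the 12 climatological months of (tmax + tmin) / 2.
    """
    tmax = _climatological_months(series, "tmax_c")
    tmin = _climatological_months(series, "tmin_c")
    return float(np.mean((tmax + tmin) / 2.0))


def bioclim_annual_precip(series: pd.DataFrame) -> float:
    """Annual precipitation (BIO12, mm): the sum over the 12 climatological
    months of the window-mean monthly precipitation totals."""
    precip = _climatological_months(series, "precip_mm")
    return float(np.sum(precip))


def select_climate_window(
    climate: pd.DataFrame,
    end_year: int,
    window_years: int = DEFAULT_CLIMATE_WINDOW_YEARS,
) -> pd.DataFrame:
    """Restrict a monthly series to the ``window_years`` years preceding and
    including ``end_year``."""
    lo = end_year - window_years + 1
    return climate[(climate["year"] >= lo) & (climate["year"] <= end_year)]


def zscore(values: np.ndarray | pd.Series, ddof: int = 1) -> np.ndarray:
    """Standardize one value per society: (x - mean) / sd.

    Uses the sample standard deviation (``ddof=1``) by default; the set of
    society values is unweighted.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise CovariateError("need at least 2 values to z-score")
    sd = float(np.std(x, ddof=ddof))
    if sd == 0.0:
        raise CovariateError("zero variance: cannot z-score a constant vector")
    return (x - np.mean(x)) / sd


def add_zscores(profiles: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Append z-scored versions of the continuous society covariates.

    A covariate that is constant across societies carries no between-society
    information; its standardized column is set to zero with a warning
    rather than failing the whole profile build.
    """
    out = profiles.copy()
    for col in ZSCORED_COLUMNS:
        if col in out.columns:
            x = out[col].to_numpy(dtype=float)
            if x.size < 2 or np.std(x, ddof=ddof) == 0.0:
                logger.warning("covariate %r is constant; z-scores set to 0", col)
                out[f"{col}_z"] = 0.0
            else:
                out[f"{col}_z"] = zscore(x, ddof=ddof)
    return out


def build_society_profiles(
    diet: pd.DataFrame,
    mammals: pd.DataFrame,
    static: pd.DataFrame,
    climate: pd.DataFrame | None = None,
    climate_end_year: int | dict[str, int] | None = None,
    window_years: int = DEFAULT_CLIMATE_WINDOW_YEARS,
    manual_mammal_class: dict[str, str] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Assemble one :class:`SocietyProfile`-shaped row per society.

    ``static`` may carry precomputed ``annual_mean_temp`` / ``annual_precip``
    columns; otherwise they are derived from ``climate``.
    """
    manual_mammal_class = manual_mammal_class or {}
    rows = []
    for society_id, grp in diet.groupby("society_id"):
        ests = [
            DietarySourceEstimate(
                source=str(r.source),
                division_score=float(r.division_score),
                mean_pct=None if pd.isna(getattr(r, "mean_pct", np.nan)) else float(r.mean_pct),
                min_pct=None if pd.isna(getattr(r, "min_pct", np.nan)) else float(r.min_pct),
                max_pct=None if pd.isna(getattr(r, "max_pct", np.nan)) else float(r.max_pct),
            )
            for r in grp.itertuples()
        ]
        props = normalize_diet(ests)
        scores = {str(r.source): float(r.division_score) for r in grp.itertuples()}
        rows.append(
            {
                "society_id": society_id,
                "prop_non_foraged": prop_non_foraged(props),
                "gendered_division": gendered_division(props, scores),
            }
        )
    out = pd.DataFrame(rows)

    dens_rows = []
    for society_id, grp in mammals.groupby("society_id"):
        if society_id in manual_mammal_class:
            cls = manual_mammal_class[society_id]
            total = float(grp["density_n_per_km2"].sum())
        else:
            cls, total = classify_mammal_density(grp["density_n_per_km2"].tolist())
        dens_rows.append(
            {
                "society_id": society_id,
                "mammal_density_class": cls,
                "mammal_density_total": total,
            }
        )
    out = out.merge(pd.DataFrame(dens_rows), on="society_id", how="left")

    static = static.rename(columns={"npp_gc_m2_yr": "npp"})
    out = out.merge(static, on="society_id", how="left")
    bad_water = out[~out["water_rating"].isin(WATER_RATINGS)]
    if len(bad_water):
        raise CovariateError(
            f"water ratings outside the 4-point scale for {bad_water['society_id'].tolist()}"
        )

    if climate is not None:
        temps, precs = [], []
        for society_id in out["society_id"]:
            sub = climate[climate["society_id"] == society_id]
            if climate_end_year is not None:
                end = (
                    climate_end_year[society_id]
                    if isinstance(climate_end_year, dict)
                    else int(climate_end_year)
                )
                sub = select_climate_window(sub, end, window_years)
            temps.append(bioclim_annual_mean_temp(sub))
            precs.append(bioclim_annual_precip(sub))
        out["annual_mean_temp"] = temps
        out["annual_precip"] = precs

    return add_zscores(out, ddof=ddof)


def load_society_profiles(path: str | Path, restandardize: bool = False) -> pd.DataFrame:
    """Read a prepared ``society_profiles.csv``; optionally recompute z-scores
    (used by subset refits after excluding societies)."""
    df = pd.read_csv(path, dtype={"society_id": str})
    if restandardize or not any(c.endswith("_z") for c in df.columns):
        df = add_zscores(df)
    return df
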