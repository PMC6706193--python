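"""Trait-table handling, variable transforms, diet scores and productivity summaries.

The comparative dataset is one row per species: an ordinal broodmate-aggression
intensity (0 none .. 3 frequent/lethal fighting), life-history traits (clutch
size, adult body mass in g, nestling period in d), parental-care behaviour
(provisioning rate, feeding-method fraction, hunting success), distribution
descriptors (migration 0/1, breeding-season months, latitude class, maximum
altitude), diet profiles, and monthly habitat-productivity (GPP) series.

Transform conventions used throughout the analyses:

* positively skewed variables (mass, clutch, nestling period, provisioning
  rate) are natural-log transformed; hourly provisioning rates are first
  converted to circadian rates (x 24);
* proportions (feeding method, hunting success) are logit transformed after
  mapping exact 1.0 to 0.95 (and, symmetrically, exact 0.0 to 0.05);
* all model variables are Z-standardized (mean 0, sample SD 1) before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitTable",
    "DietProfile",
    "GPPSeries",
    "rate_to_daily",
    "daily_to_hourly",
    "transform_pipeline",
    "diet_breadth",
    "warm_blooded_reliance",
    "agility_score",
    "hunting_success_value",
    "gpp_summaries",
]

#: daylight hours assumed when converting circadian provisioning rates to
#: hourly ones; the tropics (|latitude| <= 23 degrees) get shorter days.
DAYLIGHT_HOURS = {"tropical": 12.0, "temperate": 14.0}

#: prey classes, in the conventional importance-rank order
PREY_CATEGORIES = (
    "bird", "mammal", "reptile", "fish", "amphibian",
    "crustacean", "insect", "worm", "carrion",
)

#: 5-point prey-agility scale: 1 = immobile (carrion, worms) .. 5 = highly
#: agile (birds)
AGILITY_CLASS = {
    "carrion": 1, "worm": 1,
    "insect": 2, "crustacean": 2,
    "reptile": 3, "amphibian": 3,
    "fish": 4, "mammal": 4,
    "bird": 5,
}

VULTURE_HUNTING_SUCCESS = 0.9


# ---------------------------------------------------------------------------
# rate conversions

def rate_to_daily(rate: float) -> float:
    """Hourly feeding rate -> circadian rate (feeds/day), multiplying by 24."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    return rate * 24.0


def daily_to_hourly(rate: float, latitude_class: str) -> float:
    """Circadian feeding rate -> hourly rate using assumed daylight duration.

    Tropical species are assumed 12 daylight hours, temperate (above 23
    degrees latitude) 14 hours.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    try:
        hours = DAYLIGHT_HOURS[latitude_class]
    except KeyError:
        raise ValueError(
            f"unknown latitude class {latitude_class!r}; expected one of "
            f"{sorted(DAYLIGHT_HOURS)}"
        )
    return rate / hours


# ---------------------------------------------------------------------------
# column transforms

def transform_pipeline(column, kind: str):
    """Apply one named transform to a column (pandas Series or array).

    kind='log'    natural log; requires strictly positive values.
    kind='logit'  ln(x / (1 - x)) after mapping 1.0 -> 0.95 and 0.0 -> 0.05.
    kind='z'      Z-standardization (mean 0, sample SD 1, ddof=1).

    Missing values pass through untouched.
    """
    s = pd.Series(column, dtype=float, copy=True)
    if kind == "log":
        bad = s.index[(s <= 0) & s.notna()].tolist()
        if bad:
            raise ValueError(f"log transform requires positive values; offending rows: {bad}")
        return np.log(s)
    if kind == "logit":
        s = s.where(s != 1.0, 0.95)
        zeros = s.index[(s == 0.0) & s.notna()].tolist()
        if zeros:
            logger.warning("logit input exactly 0 mapped to 0.05 for rows %s", zeros)
            s = s.where(s != 0.0, 0.05)
        out_of_range = s.index[((s < 0) | (s > 1)) & s.notna()].tolist()
        if out_of_range:
            raise ValueError(f"logit requires values in [0, 1]; offending rows: {out_of_range}")
        return np.log(s / (1.0 - s))
    if kind == "z":
        sd = s.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("cannot Z-standardize a constant column")
        return (s - s.mean()) / sd
    raise ValueError(f"unknown transform {kind!r}")


# ---------------------------------------------------------------------------
# trait table

#: default transform declarations for the standard column set
DEFAULT_TRANSFORMS = {
    "body_mass": "log",
    "clutch_size": "log",
    "nestling_period": "log",
    "provisioning_rate": "log",
    "feeding_method": "logit",
    "hunting_success": "logit",
}


@dataclass
class TraitTable:
    """Species x trait table with transform declarations and provenance.

    ``data`` is indexed by species label (matching tree tips).  ``transforms``
    maps column name -> 'log' | 'logit' (Z-standardization is applied by the
    fitting layer, on the analysis subset).  ``transform_log`` records which
    operations have been applied to which columns.
    """

    data: pd.DataFrame
    transforms: dict = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    transform_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate species rows: {dupes}")
        if "aggression" in self.data.columns:
            vals = self.data["aggression"].dropna()
            if not vals.isin([0, 1, 2, 3]).all():
                raise ValueError("aggression must be on the 0-3 ordinal scale")
        for col in ("feeding_method", "hunting_success"):
            if col in self.data.columns:
                vals = self.data[col].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise ValueError(f"{col} must be a fraction in [0, 1]")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def missingness(self) -> pd.Series:
        """Observed (non-missing) count per column."""
        return self.data.notna().sum()

    def transformed(self, columns: list[str]) -> pd.DataFrame:
        """Return the requested columns with their declared transforms applied."""
        out = {}
        for col in columns:
            if col not in self.data.columns:
                raise KeyError(f"column {col!r} not in trait table")
            kind = self.transforms.get(col)
            if kind:
                out[col] = transform_pipeline(self.data[col], kind)
                self.transform_log.append((col, kind))
            else:
                out[col] = self.data[col].astype(float)
        return pd.DataFrame(out, index=self.data.index)

    @classmethod
    def from_csv(cls, path, transforms: dict | None = None) -> "TraitTable":
        df = pd.read_csv(path, index_col=0)
        return cls(df, transforms=dict(transforms) if transforms else dict(DEFAULT_TRANSFORMS))

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


# ---------------------------------------------------------------------------
# diet

@dataclass
class DietProfile:
    """Ranked prey-class profile for one species.

    ``ranks`` maps prey category -> importance rank (1 = most important).
    Categories must be unique and drawn from the nine standard prey classes.
    """

    ranks: dict

    def __post_init__(self) -> None:
        unknown = sorted(set(self.ranks) - set(PREY_CATEGORIES))
        if unknown:
            raise ValueError(f"unknown prey categories: {unknown}")
        for cat, r in self.ranks.items():
            if not (isinstance(r, (int, np.integer)) and r >= 1):
                raise ValueError(f"rank for {cat!r} must be a positive integer, got {r!r}")

    @property
    def categories(self) -> list[str]:
        return list(self.ranks)


def diet_breadth(diet: DietProfile) -> int:
    """Number of prey classes present in the diet."""
    return len(diet.ranks)


def warm_blooded_reliance(diet: DietProfile) -> float:
    """Mean importance rank of mammal and bird prey (1-9; lower = more reliant).

    If only one of the two classes is consumed its single rank is used; if
    neither is present the score is missing (NaN), never zero.
    """
    ranks = [diet.ranks[c] for c in ("mammal", "bird") if c in diet.ranks]
    if not ranks:
        return float("nan")
    if len(ranks) == 1:
        logger.debug("warm-blooded reliance from a single prey class: %s", diet.ranks)
    return float(np.mean(ranks))


def agility_score(diet: DietProfile, weights: dict | None = None) -> float:
    """Weighted mean prey agility on the 1-5 scale.

    Default weights are inverse importance ranks (1/r), normalized: the most
    important prey class dominates the mean.  An explicit ``weights`` dict
    (category -> nonnegative weight) overrides the default.
    """
    if not diet.ranks:
        return float("nan")
    if weights is None:
        weights = {c: 1.0 / r for c, r in diet.ranks.items()}
    w = np.array([weights.get(c, 0.0) for c in diet.categories], dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() == 0:
        raise ValueError("weights must not all be zero")
    a = np.array([AGILITY_CLASS[c] for c in diet.categories], dtype=float)
    return float(np.sum(w * a) / w.sum())


def hunting_success_value(raw: float | None, is_vulture: bool = False) -> float:
    """Hunting-success fraction, imputing the maximum (0.9) for vultures."""
    if is_vulture:
        return VULTURE_HUNTING_SUCCESS
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return float("nan")
    if not (0.0 <= raw <= 1.0):
        raise ValueError(f"hunting success must be in [0, 1], got {raw}")
    return float(raw)


# ---------------------------------------------------------------------------
# habitat productivity (GPP) series

@dataclass
class GPPSeries:
    """Monthly habitat-productivity values on a years x 12 grid.

    ``values`` has shape (n_years, 12); ``breeding_months`` is a list of month
    indices (0-11) defining the breeding season.  Values are nonnegative
    productivity units.
    """

    values: np.ndarray
    breeding_months: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 12:
            raise ValueError("values must be a (n_years, 12) grid")
        if np.any(self.values < 0):
            raise ValueError("productivity values must be nonnegative")
        if any(m < 0 or m > 11 for m in self.breeding_months):
            raise ValueError("breeding months must be indices 0-11")

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_row(cls, row: np.ndarray, breeding_mask: str, n_years: int = 15) -> "GPPSeries":
        """Build from a flat 180-value row and a 'start-end' month mask like '3-7'.

        Months in the mask are 1-based and inclusive; a wrap-around window
        like '11-2' is supported.
        """
        vals = np.asarray(row, dtype=float).reshape(n_years, 12)
        start_s, end_s = breeding_mask.split("-")
        start, end = int(start_s) - 1, int(end_s) - 1
        if start <= end:
            months = list(range(start, end + 1))
        else:
            months = list(range(start, 12)) + list(range(0, end + 1))
        return cls(vals, months)


def gpp_summaries(series: GPPSeries, include_breeding: bool | None = None) -> dict:
    """Productivity and stability summaries of a monthly GPP series.

    Returns mean/min/max over all months, the breeding-season mean,
    within-year seasonality (mean annual range and mean within-year SD), and
    between-year variability (SD across years of the yearly minima and maxima,
    SD of all breeding-month values, SD of all values).  SDs are sample SDs
    (ddof=1) throughout.

    ``include_breeding=None`` includes the breeding summaries whenever a
    breeding-month mask is set; requesting them explicitly (``True``) with an
    empty mask is an error.
    """
    if include_breeding is None:
        include_breeding = bool(series.breeding_months)
    if include_breeding and not series.breeding_months:
        raise ValueError("breeding summaries requested but breeding-month mask is empty")
    v = series.values
    yearly_min = v.min(axis=1)
    yearly_max = v.max(axis=1)
    out = {
        "mean_gpp": float(v.mean()),
        "min_gpp": float(v.min()),
        "max_gpp": float(v.max()),
        "annual_range_gpp": float((yearly_max - yearly_min).mean()),
        "annual_sd_gpp": float(np.mean(np.std(v, axis=1, ddof=1))),
        "sd_min_gpp": float(np.std(yearly_min, ddof=1)),
        "sd_max_gpp": float(np.std(yearly_max, ddof=1)),
        "sd_gpp_all": float(np.std(v.ravel(), ddof=1)),
    }
    if include_breeding:
        breeding = v[:, series.breeding_months]
        out["mean_gpp_breeding"] = float(breeding.mean())
        out["sd_gpp_breeding"] = float(np.std(breeding.ravel(), ddof=1))
    return out
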