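"""Quantification of lifestyle questionnaire answers.

The drinking exposure comes from two multiple-choice items — a daily-volume
band ("how much do you drink?") and a frequency band ("how often do you
drink?").  Weekly ethanol grams are the product of the two band means, and
subjects fall into never/light/moderate/heavy strata by weekly grams.  The
band means and the two stratum cutoffs are configuration, since questionnaire
band edges vary between checkup programs; the defaults below use arithmetic
band midpoints, a 100 g/week light/moderate cutoff and a 350 g/week
moderate/heavy cutoff ("heavy" = more than 350 g per week).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import CohortTable, VariableDescriptor

DRINKING_CATEGORIES = ("never", "light", "moderate", "heavy")

#: grams of ethanol per day for each volume answer band (midpoint of the band;
#: the open top band uses its lower edge plus half the preceding band's width)
DEFAULT_VOLUME_MEANS: Mapping[str, float] = {
    "none": 0.0,
    "<20 g/day": 10.0,
    "21-40 g/day": 30.5,
    "41-60 g/day": 50.5,
    ">60 g/day": 70.0,
}

#: drinking days per week for each frequency answer band
DEFAULT_FREQUENCY_MEANS: Mapping[str, float] = {
    "never": 0.0,
    "few times/month": 0.5,
    "1-2 days/week": 1.5,
    "3-4 days/week": 3.5,
    "5-6 days/week": 5.5,
    "every day": 7.0,
}


@dataclass(frozen=True)
class CategoryQuantificationConfig:
    """Band means and stratum cutoffs used to quantify drinking answers."""

    volume_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VOLUME_MEANS)
    )
    frequency_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_MEANS)
    )
    category_cutoffs: tuple[float, float] = (100.0, 350.0)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.volume_means.values()):
            raise ValueError("volume band means must be non-negative")
        if any(v < 0 for v in self.frequency_means.values()):
            raise ValueError("frequency band means must be non-negative")
        lo, hi = self.category_cutoffs
        if not 0 < lo < hi:
            raise ValueError("category cutoffs must be strictly increasing and positive")


DEFAULT_QUANTIFICATION = CategoryQuantificationConfig()


@dataclass(frozen=True)
class DrinkingProfile:
    """One subject's quantified drinking exposure."""

    volume_category: str
    frequency_category: str
    weekly_grams: float
    category: str


def quantify_weekly_alcohol(
    volume_category: str,
    frequency_category: str,
    config: CategoryQuantificationConfig = DEFAULT_QUANTIFICATION,
) -> float:
    """Weekly ethanol grams = volume band mean (g/day) x frequency band mean (days/week)."""
    if volume_category not in config.volume_means:
        raise ValueError(f"unknown volume answer {volume_category!r}")
    if frequency_category not in config.frequency_means:
        raise ValueError(f"unknown frequency answer {frequency_category!r}")
    freq = config.frequency_means[frequency_category]
    if freq == 0.0:
        return 0.0
    return config.volume_means[volume_category] * freq


def assign_drinking_category(
    weekly_grams: float,
    config: CategoryQuantificationConfig = DEFAULT_QUANTIFICATION,
) -> str:
    """Map weekly grams to never / light / moderate / heavy.

    Bands are lower-open, upper-closed: 0 -> never, (0, c1] -> light,
    (c1, c2] -> moderate, > c2 -> heavy (so "more than c2 grams" is heavy).
    """
    if not np.isfinite(weekly_grams) or weekly_grams < 0:
        raise ValueError(f"weekly grams must be finite and non-negative, got {weekly_grams}")
    c1, c2 = config.category_cutoffs
    if weekly_grams == 0:
        return "never"
    if weekly_grams <= c1:
        return "light"
    if weekly_grams <= c2:
        return "moderate"
    return "heavy"


def drinking_profile(
    volume_category: str,
    frequency_category: str,
    config: CategoryQuantificationConfig = DEFAULT_QUANTIFICATION,
) -> DrinkingProfile:
    grams = quantify_weekly_alcohol(volume_category, frequency_category, config)
    return DrinkingProfile(
        volume_category, frequency_category, grams, assign_drinking_category(grams, config)
    )


def encode_answer_numeric(value, descriptor: VariableDescriptor) -> float:
    """Encode one raw answer to the numeric scale used by the correlation screen.

    Continuous values pass through; binary maps to 0/1 by declared level
    order; ordinal uses the descriptor's ``numeric_map`` when present, else
    the 1-based level rank.  Nominal multi-level variables without a
    ``numeric_map`` are rejected — there is no defensible order to impose.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    kind = descriptor.kind
    if kind == "continuous":
        return float(value)
    value = str(value)
    if value not in descriptor.ordinal_levels:
        raise ValueError(f"undeclared level {value!r} for {descriptor.name!r}")
    if descriptor.numeric_map is not None and value in descriptor.numeric_map:
        return float(descriptor.numeric_map[value])
    if kind == "binary":
        return float(descriptor.ordinal_levels.index(value))
    if kind == "ordinal":
        return float(descriptor.ordinal_levels.index(value) + 1)
    raise ValueError(
        f"nominal variable {descriptor.name!r} has more than 2 levels and no "
        "numeric_map; supply a numeric_map or exclude it from the screen"
    )


def encode_table(table: CohortTable, exclude: tuple[str, ...] = ()) -> pd.DataFrame:
    """Encode a whole cohort table to floats (NaN marks missing)."""
    out = {}
    for desc in table.variables:
        if desc.name in exclude:
            continue
        col = table.data[desc.name]
        if desc.kind == "continuous":
            out[desc.name] = col.astype(float)
        else:
            out[desc.name] = col.map(
                lambda v, d=desc: encode_answer_numeric(v, d)
            ).astype(float)
    return pd.DataFrame(out, index=table.data.index)


def quantify_table(
    table: CohortTable,
    volume_col: str = "alcohol_volume_level",
    frequency_col: str = "alcohol_frequency_level",
    config: CategoryQuantificationConfig = DEFAULT_QUANTIFICATION,
    grams_col: str = "alcohol_weekly_g",
    category_col: str = "drinking_category",
) -> CohortTable:
    """Append (or overwrite) weekly-grams and drinking-category columns."""
    vol = table.data[volume_col]
    freq = table.data[frequency_col]
    grams, cats = [], []
    for v, f in zip(vol, freq):
        if pd.isna(v) or pd.isna(f):
            grams.append(np.nan)
            cats.append(np.nan)
        else:
            g = quantify_weekly_alcohol(str(v), str(f), config)
            grams.append(g)
            cats.append(assign_drinking_category(g, config))
    data = table.data.copy()
    data[grams_col] = grams
    data[category_col] = cats
    keep = [v for v in table.variables if v.name not in (grams_col, category_col)]
    schema = tuple(keep) + (
        VariableDescriptor(grams_col, "continuous", units="g/week"),
        VariableDescriptor(category_col, "ordinal", ordinal_levels=DRINKING_CATEGORIES),
    )
    data = data[[v.name for v in schema]]
    return CohortTable(data, schema, table.timepoint)
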