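"""Baseline unit value and the three multiplicative adjustment factors.

The per-hectare value of every service is anchored to the food-production
value of arable land (the baseline, D), transferred from the national
reference by the local/national yield ratio. Three dimensionless factors
then correct the transfer:

* NR — natural-resource productivity, the city/national NPP ratio;
* SE — ability to pay, the yearly local/national per-capita income ratio;
* S  — within-city spatiotemporal heterogeneity, each district-year's
  food yield per hectare relative to the grand mean over all
  district-years (so the factors average to exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from ._rounding import round_half_away


@dataclass(frozen=True)
class BaselineSpec:
    """Inputs of the baseline-value transfer."""

    national_unit_value: float  # yuan/hm2
    local_yield: float          # kg/hm2
    national_yield: float       # kg/hm2
    ratio_decimals: int = 4

    def __post_init__(self) -> None:
        if min(self.national_unit_value, self.local_yield, self.national_yield) <= 0:
            raise ValueError("baseline monetary and yield inputs must be positive")


def compute_baseline_unit_value(
    national_unit_value: float,
    local_yield: float,
    national_yield: float,
    ratio_decimals: int = 4,
) -> float:
    """Transfer the national baseline to the study area via the yield ratio.

    The yield ratio is rounded to ``ratio_decimals`` before multiplication,
    which is how published transfers carry the printed ratio forward; the
    product is rounded to 2 decimals (yuan cents).
    """
    spec = BaselineSpec(national_unit_value, local_yield, national_yield, ratio_decimals)
    ratio = round_half_away(spec.local_yield / spec.national_yield, spec.ratio_decimals)
    return round_half_away(spec.national_unit_value * ratio, 2)


def compute_nr(city_npp: float, national_npp: float) -> float:
    """Natural-resource factor: city NPP over national NPP (t/km2 each)."""
    if city_npp <= 0 or national_npp <= 0:
        raise ValueError("NPP values must be positive")
    return city_npp / national_npp


def compute_se(
    local_income: Mapping[int, float],
    national_income: Mapping[int, float],
) -> dict[int, float]:
    """Socioeconomic factor per year: local over national per-capita income."""
    if set(local_income) != set(national_income):
        raise ValueError("local and national income series must cover the same years")
    out = {}
    for year in sorted(local_income):
        lo, na = local_income[year], national_income[year]
        if lo <= 0 or na <= 0:
            raise ValueError(f"incomes must be positive (year {year})")
        out[year] = lo / na
    return out


def compute_s(yields: pd.DataFrame) -> pd.Series:
    """Spatiotemporal factors from a district-year yield panel.

    ``yields`` needs columns region, year, dyph (food production per
    hectare, kg/hm2, positive). Each factor is the cell yield divided by
    the grand mean over all district-year cells, so the returned factors
    average to exactly 1 and are invariant to rescaling all yields.
    """
    required = {"region", "year", "dyph"}
    if not required <= set(yields.columns):
        raise ValueError(f"yield panel needs columns {sorted(required)}")
    if yields.empty:
        raise ValueError("yield panel is empty")
    if yields.duplicated(subset=["region", "year"]).any():
        raise ValueError("duplicate (region, year) key in yield panel")
    dyph = yields.set_index(["region", "year"])["dyph"].astype(float)
    if (dyph <= 0).any() or dyph.isna().any():
        raise ValueError("all yields must be finite and positive")
    return (dyph / dyph.mean()).rename("s")


@dataclass
class AdjustmentSet:
    """NR scalar, SE by year, and optional S by (region, year)."""

    nr: float = 1.0
    se: Mapping[int, float] = field(default_factory=dict)
    s: pd.Series | Mapping[tuple[str, int], float] | None = None

    def __post_init__(self) -> None:
        if self.nr <= 0:
            raise ValueError("NR must be positive")
        for year, v in dict(self.se).items():
            if v <= 0:
                raise ValueError(f"SE must be positive (year {year})")
        if self.s is not None and not isinstance(self.s, pd.Series):
            self.s = pd.Series(dict(self.s))

    def se_for(self, year: int) -> float:
        if year not in self.se:
            raise KeyError(f"no SE factor for year {year}")
        return float(self.se[year])

    def s_for(self, region: str, year: int) -> float | None:
        """S factor, or None when the region-year is not covered."""
        if self.s is None:
            return None
        try:
            return float(self.s.loc[(region, year)])
        except KeyError:
            return None
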