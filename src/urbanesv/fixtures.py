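"""Packaged Wuhan 1996-2018 reference tables.

The bundle carries the published citywide inputs and results for Wuhan:
land-cover areas for the six survey years, the 9x11 equivalent-factor
matrix, the two literature study tables behind the artificial-cover rows,
district spatiotemporal factors, the valuation decompositions by cover and
by service, and the equivalent-factor sensitivity table, together with the
scalar study constants (baseline unit value, NR, SE series, study period).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import io

#: National baseline unit value of the food-production service (yuan/hm2)
NATIONAL_UNIT_VALUE = 3406.50
#: Mean crop yield (kg/hm2), local and national, over the study period
LOCAL_YIELD = 5577.87
NATIONAL_YIELD = 4891.84
#: Baseline unit value transferred to the study city (yuan/hm2)
D_WUHAN = 3884.09
#: Natural-resource adjustment factor (city/national NPP ratio)
NR_WUHAN = 1.01
#: Socioeconomic adjustment factors by survey year (income ratio)
SE_WUHAN: dict[int, float] = {
    1996: 1.08, 2000: 1.08, 2005: 1.05, 2010: 1.11, 2015: 1.17, 2018: 1.21,
}
#: Study period length in years
STUDY_PERIOD_T = 22
STUDY_YEARS = (1996, 2000, 2005, 2010, 2015, 2018)

#: Printed per-service mean ratios of man-made to natural wetland unit values.
#: Four of these (CR, EP, SR, AL) do not equal the mean of the printed study
#: column; the canonical matrix treats the printed row as authoritative and
#: the derivation op reports the discrepancies.
PRINTED_RATIO_MEANS: dict[str, float] = {
    "AP": 0.99, "RM": 0.71, "WS": 1.32, "GR": 0.92, "CR": 0.97, "EP": 0.84,
    "HR": 0.65, "SR": 0.39, "NC": 0.85, "BC": 0.86, "AL": 0.90,
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("urbanesv").joinpath("data", name)))


@dataclass
class WuhanFixtures:
    """Published Wuhan tables plus the scalar study constants."""

    areas: pd.DataFrame            # long area panel, region="Wuhan", 6 years x 9 types
    ef_matrix: pd.DataFrame        # 9x11 equivalent factors
    ratio_table: pd.DataFrame      # man-made/natural wetland unit-value ratios by study
    builtup_table: pd.DataFrame    # built-up equivalent factors by study
    s_factors: pd.Series           # (district, year) -> spatiotemporal factor
    land_share_pct: pd.DataFrame   # lulc x year, percent of total area
    esv_by_lulc: pd.DataFrame      # long: year, lulc (incl. "total"), esv_billion, share_pct
    esv_by_service: pd.DataFrame   # long: year, service (incl. "total"), esv_billion, share_pct
    sef_table: pd.DataFrame        # lulc x year sensitivity indices
    printed_ratio_means: dict[str, float] = field(default_factory=lambda: dict(PRINTED_RATIO_MEANS))
    se_series: dict[int, float] = field(default_factory=lambda: dict(SE_WUHAN))
    nr: float = NR_WUHAN
    d: float = D_WUHAN
    t: int = STUDY_PERIOD_T

    def esv_decomposition(self, year: int) -> pd.Series:
        """Published per-cover ESV (billion yuan) for one year, without the total."""
        df = self.esv_by_lulc
        sub = df[(df["year"] == year) & (df["lulc"] != "total")]
        if sub.empty:
            raise KeyError(f"no decomposition for year {year}")
        return sub.set_index("lulc")["esv_billion"]

    def esv_total(self, year: int) -> float:
        df = self.esv_by_lulc
        row = df[(df["year"] == year) & (df["lulc"] == "total")]
        if row.empty:
            raise KeyError(f"no total for year {year}")
        return float(row["esv_billion"].iloc[0])


def load_wuhan() -> WuhanFixtures:
    """Load the packaged Wuhan fixture bundle."""
    def wide(name: str) -> pd.DataFrame:
        df = pd.read_csv(_data_path(name)).set_index("lulc")
        df.columns = df.columns.astype(int)
        return df

    return WuhanFixtures(
        areas=io.read_area_panel(_data_path("wuhan_areas.csv")),
        ef_matrix=io.read_ef_matrix(_data_path("ef_matrix.csv")),
        ratio_table=io.read_study_table(_data_path("manmade_ratio_studies.csv")),
        builtup_table=io.read_study_table(_data_path("builtup_value_studies.csv")),
        s_factors=io.read_s_factors(_data_path("s_factors.csv")),
        land_share_pct=wide("land_share_pct.csv"),
        esv_by_lulc=pd.read_csv(_data_path("esv_by_lulc.csv")),
        esv_by_service=pd.read_csv(_data_path("esv_by_service.csv")),
        sef_table=wide("sef_table.csv"),
    )


def export_fixtures(outdir: str | Path) -> list[Path]:
    """Copy every packaged fixture CSV into ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in (
        "wuhan_areas.csv", "ef_matrix.csv", "manmade_ratio_studies.csv",
        "builtup_value_studies.csv", "s_factors.csv", "land_share_pct.csv",
        "esv_by_lulc.csv", "esv_by_service.csv", "sef_table.csv",
    ):
        target = outdir / name
        target.write_text(_data_path(name).read_text())
        written.append(target)
    return written
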