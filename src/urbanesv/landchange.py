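"""Land-cover change rate and the single-type dynamic index K.

The change rate of cover k over [t0, t1] is (A1 - A0)/A0 * 100 percent;
the dynamic index K annualizes it, K = change_rate / T with T = t1 - t0
years. Both are invariant to area-unit rescaling and K * T recovers the
change rate exactly.
"""

from __future__ import annotations

import pandas as pd

from .io import validate_area_panel


def _area_at(panel: pd.DataFrame, lulc: str, year: int, region: str | None) -> float:
    sub = panel[(panel["lulc"] == lulc) & (panel["year"] == year)]
    if region is not None:
        sub = sub[sub["region"] == region]
    if sub.empty:
        raise KeyError(f"no area record for ({region or 'any region'}, {year}, {lulc})")
    return float(sub["area_ha"].sum())


def area_change_rate(
    panel: pd.DataFrame, lulc: str, t0: int, t1: int, region: str | None = None
) -> float:
    """Percent area change of one cover between two years."""
    panel = validate_area_panel(panel)
    a0 = _area_at(panel, lulc, t0, region)
    a1 = _area_at(panel, lulc, t1, region)
    if a0 == 0:
        raise ZeroDivisionError(f"change rate undefined: zero area for {lulc} at {t0}")
    return (a1 - a0) / a0 * 100.0


def dynamic_index_k(
    panel: pd.DataFrame, lulc: str, t0: int, t1: int, region: str | None = None
) -> float:
    """Annualized change rate (percent per year) over T = t1 - t0 years."""
    if t1 - t0 < 1:
        raise ValueError("period must span at least one year")
    return area_change_rate(panel, lulc, t0, t1, region) / (t1 - t0)


def change_table(
    panel: pd.DataFrame,
    intervals: list[tuple[int, int]],
    region: str | None = None,
) -> pd.DataFrame:
    """Change rate and K for every cover over each (t0, t1) interval.

    Returns a frame indexed by lulc with a two-level column index
    (interval label, {"change_rate", "k"}); covers with zero initial area
    get NaN for that interval.
    """
    panel = validate_area_panel(panel)
    types = sorted(panel["lulc"].unique(), key=list(panel["lulc"]).index)
    blocks = {}
    for t0, t1 in intervals:
        label = f"{t0}-{t1}"
        rates, ks = [], []
        for lulc in types:
            try:
                r = area_change_rate(panel, lulc, t0, t1, region)
            except ZeroDivisionError:
                r = float("nan")
            rates.append(r)
            ks.append(r / (t1 - t0))
        blocks[(label, "change_rate")] = rates
        blocks[(label, "k")] = ks
    return pd.DataFrame(blocks, index=pd.Index(types, name="lulc"))


def land_shares(panel: pd.DataFrame, region: str | None = None) -> pd.DataFrame:
    """Percent of total area by cover and year (index lulc, columns year)."""
    panel = validate_area_panel(panel)
    if region is not None:
        panel = panel[panel["region"] == region]
    wide = panel.pivot_table(index="lulc", columns="year", values="area_ha", aggfunc="sum")
    return wide / wide.sum(axis=0) * 100.0
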