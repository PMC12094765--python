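"""Sensitivity of total ESV to each cover's equivalent factors.

The sensitivity index for cover k perturbs all eleven of its equivalent
factors jointly by a fraction delta (conventionally +/-50%) and measures
the elasticity

    SEF(k) = |(ESV' - ESV)/ESV| / |delta|.

Because the valuation is linear in equivalent factors, the perturbed total
is ESV + delta * ESV_k exactly, so SEF(k) = |ESV_k| / |ESV_total| for any
nonzero delta: the index is the cover's absolute share of the total. A
cover is inelastic when 0 < SEF <= 1 (the total is robust to its factors)
and elastic above 1.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd


def sef(
    decomposition: Mapping[str, float] | pd.Series,
    lulc: str,
    delta: float = 0.5,
    total: float | None = None,
) -> float:
    """Sensitivity index of one cover from a per-cover ESV decomposition.

    ``decomposition`` maps each cover to its ESV contribution in one year
    (any consistent monetary unit). ``delta`` is the fractional factor
    perturbation; it must be nonzero but does not affect the result.
    ``total`` overrides the denominator (useful when components were
    rounded independently of a published total); default is the component
    sum.
    """
    if delta == 0:
        raise ValueError("delta must be nonzero")
    decomposition = pd.Series(decomposition, dtype=float)
    if lulc not in decomposition.index:
        raise KeyError(lulc)
    if total is None:
        total = decomposition.sum()
    if total == 0:
        raise ZeroDivisionError("total ESV is zero; sensitivity undefined")
    # |(delta * ESV_k / total)| / |delta| collapses to the absolute share,
    # which is also exactly invariant to the perturbation size
    return abs(float(decomposition[lulc]) / total)


def sef_table(
    by_lulc: pd.DataFrame,
    deltas: Iterable[float] = (0.5,),
    totals: Mapping[int, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Full (lulc, year) sensitivity grid from a year x lulc margin.

    ``by_lulc`` is the per-year decomposition (index year, columns lulc),
    e.g. ``ESVSummary.by_lulc``. Every delta in ``deltas`` is evaluated and
    must agree (they do, by linearity); the shared grid is returned with
    covers as rows, years as columns. ``totals`` optionally fixes the
    per-year denominators. Elasticity flags come from
    :func:`classify_elasticity`.
    """
    deltas = list(deltas)
    if not deltas:
        raise ValueError("at least one delta required")
    grids = []
    for delta in deltas:
        grid = pd.DataFrame(
            {year: {k: sef(row, k, delta,
                           total=None if totals is None else float(totals[year]))
                    for k in row.index}
             for year, row in by_lulc.iterrows()}
        )
        grids.append(grid)
    first = grids[0]
    for other in grids[1:]:
        pd.testing.assert_frame_equal(first, other)
    return first.loc[list(by_lulc.columns), list(by_lulc.index)].rename_axis("lulc")


def classify_elasticity(sef_grid: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Boolean grid: True where the index exceeds the elasticity threshold."""
    return sef_grid > threshold
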