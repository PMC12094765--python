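"""Meta-analytic derivation of equivalent factors for artificial land covers.

Classical equivalent-factor tables price only natural covers. The two
artificial classes are filled in by unweighted meta-analysis of published
case studies:

* man-made wetland — per-service mean of published man-made/natural
  unit-value ratios, multiplied by the natural-wetland factor row;
* built-up area — per-service mean of published built-up equivalent
  factors (negative values encode disservices).

Means are rounded half-away-from-zero at the reporting precision before
multiplication, matching how published average rows are carried forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import pandas as pd

from ._rounding import round_half_away
from .catalogs import ADOPTED_TYPES, DEFAULT_LULC, DERIVED_TYPES, SERVICES

MissingPolicy = Literal["skip", "zero_fill"]


def column_means(
    table: pd.DataFrame,
    missing_policy: MissingPolicy = "skip",
    round_to: int = 2,
) -> pd.Series:
    """Per-service unweighted mean over study rows.

    Under ``skip`` blank cells are excluded from the denominator; under
    ``zero_fill`` they count as zeros. Printed zeros always count. The
    result is rounded half-away-from-zero to ``round_to`` decimals.
    """
    if round_to < 0:
        raise ValueError("round_to must be >= 0")
    cols = [s for s in SERVICES if s in table.columns]
    out = {}
    for svc in cols:
        col = table[svc]
        if missing_policy == "zero_fill":
            col = col.fillna(0.0)
        else:
            col = col.dropna()
            if col.empty:
                raise ValueError(f"service column {svc!r} is entirely missing under skip policy")
        out[svc] = round_half_away(col.mean(), round_to)
    return pd.Series(out, name="mean")


def derive_manmade_ef(
    means: Mapping[str, float] | pd.Series,
    natural_row: Mapping[str, float] | pd.Series,
    round_to: int = 2,
) -> pd.Series:
    """Equivalent factors of man-made wetland: mean ratio x natural-wetland EF."""
    means = pd.Series(means)
    natural_row = pd.Series(natural_row)
    missing = [s for s in SERVICES if s not in means.index or s not in natural_row.index]
    if missing:
        raise ValueError(f"service(s) {missing} missing from ratio means or natural row")
    ef = {s: round_half_away(float(means[s]) * float(natural_row[s]), round_to) for s in SERVICES}
    return pd.Series(ef, name="manmade_wetland")


def derive_builtup_ef(
    table: pd.DataFrame,
    missing_policy: MissingPolicy = "skip",
    round_to: int = 2,
) -> pd.Series:
    """Equivalent factors of built-up land: per-service mean of literature values."""
    row = column_means(table, missing_policy=missing_policy, round_to=round_to)
    row.name = "builtup"
    return row


def ratio_mean_discrepancies(
    table: pd.DataFrame,
    printed_means: Mapping[str, float],
    missing_policy: MissingPolicy = "skip",
    round_to: int = 2,
) -> pd.DataFrame:
    """Compare recomputed per-service means against a published average row.

    Published average rows occasionally disagree with the mean of their own
    printed column (transcription or column-alignment slips in the source
    literature). Rather than silently overriding either side, the derivation
    path surfaces the disagreement for the analyst.
    """
    computed = column_means(table, missing_policy=missing_policy, round_to=round_to)
    rows = []
    for svc in SERVICES:
        if svc not in printed_means:
            continue
        c, p = float(computed[svc]), float(printed_means[svc])
        if abs(c - p) > 0.5 * 10 ** -round_to:
            rows.append({"service": svc, "computed_mean": c, "printed_mean": p,
                         "difference": round_half_away(c - p, round_to + 2)})
    return pd.DataFrame(rows, columns=["service", "computed_mean", "printed_mean", "difference"])


@dataclass
class EFMatrix:
    """A complete 9x11 equivalent-factor matrix with row provenance."""

    table: pd.DataFrame
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        from .io import validate_ef_matrix

        self.table = validate_ef_matrix(self.table)


def assemble_ef_matrix(
    adopted_rows: pd.DataFrame,
    manmade_row: Mapping[str, float] | pd.Series,
    builtup_row: Mapping[str, float] | pd.Series,
) -> EFMatrix:
    """Assemble the full matrix from adopted rows plus the two derived rows."""
    adopted_rows = pd.DataFrame(adopted_rows)
    extra = [t for t in adopted_rows.index if t not in ADOPTED_TYPES]
    if extra:
        raise ValueError(f"row(s) {extra} overlap the derived types or are unknown")
    missing = [t for t in ADOPTED_TYPES if t not in adopted_rows.index]
    if missing:
        raise ValueError(f"adopted rows missing type(s) {missing}")
    full = pd.concat(
        [
            adopted_rows,
            pd.Series(manmade_row, name="manmade_wetland").to_frame().T,
            pd.Series(builtup_row, name="builtup").to_frame().T,
        ]
    ).loc[list(DEFAULT_LULC.types), list(SERVICES)]
    provenance = {t: "adopted" for t in ADOPTED_TYPES}
    provenance["manmade_wetland"] = "derived-meta"
    provenance["builtup"] = "derived-builtup"
    assert set(provenance) == set(DEFAULT_LULC.types) and set(DERIVED_TYPES) <= set(provenance)
    return EFMatrix(table=full.astype(float), provenance=provenance)
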