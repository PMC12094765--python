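"""Unit-value valuation: the ESV cube and its aggregation margins.

The value of service i on cover k in region r and year t is

    ESV(r,t,k,i) = A(r,t,k) * D * EF(k,i) * NR * SE(t) * S(r,t)

with A the area (hm2), D the baseline unit value (yuan/hm2), EF the
dimensionless equivalent factor, and NR/SE/S the adjustment factors.
The model is linear in areas and in equivalent factors, so every margin
(by cover, by service, by category, totals) is an exact sum of cube cells.

``UnitValueModel`` exposes the evaluation as a scikit-learn style
transformer (an area panel in, the long-format cube out); the module
functions are thin wrappers over it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .adjustment import AdjustmentSet
from .catalogs import SERVICE_CATEGORIES, SERVICES
from .io import validate_area_panel, validate_ef_matrix

logger = logging.getLogger(__name__)


class UnitValueModel(BaseEstimator, TransformerMixin):
    """Benefit-transfer valuation of an area panel.

    Parameters
    ----------
    ef_matrix : DataFrame
        9x11 equivalent factors (rows = lulc, columns = services).
    d : float
        Baseline unit value, yuan/hm2.
    nr : float
        Natural-resource adjustment factor.
    se : mapping year -> float
        Socioeconomic adjustment factors; every year in the panel must be
        covered.
    s : Series indexed by (region, year), optional
        Spatiotemporal factors; absent region-years fall back to 1 (logged).
    """

    def __init__(self, ef_matrix=None, d=1.0, nr=1.0, se=None, s=None):
        self.ef_matrix = ef_matrix
        self.d = d
        self.nr = nr
        self.se = se
        self.s = s

    def fit(self, X=None, y=None):
        if self.ef_matrix is None:
            raise ValueError("ef_matrix is required")
        if self.d <= 0:
            raise ValueError("baseline unit value d must be positive")
        self.ef_matrix_ = validate_ef_matrix(pd.DataFrame(self.ef_matrix))
        self.adjustments_ = AdjustmentSet(nr=self.nr, se=dict(self.se or {}), s=self.s)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Evaluate the cube for a long-format area panel.

        Returns a long DataFrame (region, year, lulc, service, value_yuan)
        with one row per populated (region, year, lulc) and service.
        """
        if not hasattr(self, "ef_matrix_"):
            self.fit()
        areas = validate_area_panel(X)
        missing_ef = set(areas["lulc"]) - set(self.ef_matrix_.index)
        if missing_ef:
            raise ValueError(f"EF matrix missing populated type(s) {sorted(missing_ef)}")

        adj = self.adjustments_
        se = areas["year"].map(lambda t: adj.se_for(int(t))) if adj.se else pd.Series(1.0, index=areas.index)
        if adj.s is not None:
            s = pd.Series(
                [adj.s_for(r, int(t)) for r, t in zip(areas["region"], areas["year"])],
                index=areas.index,
            )
            n_default = int(s.isna().sum())
            if n_default:
                logger.warning("S factor absent for %d area record(s); defaulting to 1", n_default)
            s = s.astype(float).fillna(1.0)
        else:
            s = pd.Series(1.0, index=areas.index)

        base = areas["area_ha"].to_numpy() * self.d * adj.nr * se.to_numpy() * s.to_numpy()
        ef = self.ef_matrix_.loc[areas["lulc"], list(SERVICES)].to_numpy()
        values = base[:, None] * ef

        cube = areas.loc[:, ["region", "year", "lulc"]].copy()
        cube = cube.loc[cube.index.repeat(len(SERVICES))].reset_index(drop=True)
        cube["service"] = list(SERVICES) * len(areas)
        cube["value_yuan"] = values.ravel()
        if not np.isfinite(cube["value_yuan"]).all():
            raise ValueError("non-finite value in ESV cube")
        return cube


def compute_esv_cube(
    areas: pd.DataFrame,
    ef: pd.DataFrame,
    d: float,
    adj: AdjustmentSet | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`UnitValueModel`."""
    adj = adj or AdjustmentSet()
    model = UnitValueModel(ef_matrix=ef, d=d, nr=adj.nr, se=dict(adj.se), s=adj.s).fit()
    return model.transform(areas)


@dataclass
class ESVSummary:
    """Aggregation margins and change statistics of an ESV cube.

    Monetary frames are in yuan; ``p_*`` frames are percent of the year
    total; change frames have rows vc (value change, yuan), cr (percent
    change) and add (annual rate, percent/yr = cr / T).
    """

    by_lulc: pd.DataFrame       # index year, columns lulc
    by_service: pd.DataFrame    # index year, columns service
    by_category: pd.DataFrame   # index year, columns category
    totals: pd.Series           # index year
    p_lulc: pd.DataFrame
    p_service: pd.DataFrame
    change_by_lulc: pd.DataFrame     # rows vc/cr/add, columns lulc + total
    change_by_service: pd.DataFrame  # rows vc/cr/add, columns service + total
    t0: int
    t1: int
    period_t: float


def _change_frame(margin: pd.DataFrame, totals: pd.Series, t0: int, t1: int, period: float) -> pd.DataFrame:
    cols = list(margin.columns) + ["total"]
    v0 = pd.concat([margin.loc[t0], pd.Series({"total": totals.loc[t0]})])
    v1 = pd.concat([margin.loc[t1], pd.Series({"total": totals.loc[t1]})])
    vc = v1 - v0
    # percent change against the magnitude of the initial value: a further
    # decline of a negative contribution (built-up) reports as negative
    with np.errstate(divide="ignore", invalid="ignore"):
        cr = np.where(v0 != 0, vc / np.abs(v0) * 100.0, np.nan)
    cr = pd.Series(cr, index=vc.index)
    add = cr / period
    return pd.DataFrame([vc, cr, add], index=["vc", "cr", "add"])[cols]


def summarize(cube: pd.DataFrame, t0: int, t1: int, period_t: float | None = None) -> ESVSummary:
    """Margins, proportions and t0->t1 change statistics of a cube.

    ``period_t`` defaults to ``t1 - t0`` years. Where a t0 value is zero the
    percent change (and hence the annual rate) is undefined and reported as
    NaN rather than +/-inf.
    """
    if t0 >= t1:
        raise ValueError("t0 must precede t1")
    years = set(cube["year"])
    if t0 not in years or t1 not in years:
        raise ValueError(f"cube lacks year {t0 if t0 not in years else t1}")
    period = float(period_t if period_t is not None else t1 - t0)

    by_lulc = cube.pivot_table(index="year", columns="lulc", values="value_yuan", aggfunc="sum")
    by_service = cube.pivot_table(index="year", columns="service", values="value_yuan", aggfunc="sum")
    by_service = by_service[[s for s in SERVICES if s in by_service.columns]]
    totals = by_lulc.sum(axis=1)
    by_category = pd.DataFrame(
        {cat: by_service[[s for s in members if s in by_service.columns]].sum(axis=1)
         for cat, members in SERVICE_CATEGORIES.items()}
    )
    p_lulc = by_lulc.div(totals, axis=0) * 100.0
    p_service = by_service.div(totals, axis=0) * 100.0
    return ESVSummary(
        by_lulc=by_lulc,
        by_service=by_service,
        by_category=by_category,
        totals=totals,
        p_lulc=p_lulc,
        p_service=p_service,
        change_by_lulc=_change_frame(by_lulc, totals, t0, t1, period),
        change_by_service=_change_frame(by_service, totals, t0, t1, period),
        t0=t0,
        t1=t1,
        period_t=period,
    )


def to_billions(x: pd.DataFrame | pd.Series | float, decimals: int = 2):
    """Reporting helper: yuan -> 1e9 yuan, rounded."""
    return (x / 1e9).round(decimals) if not np.isscalar(x) else round(x / 1e9, decimals)
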