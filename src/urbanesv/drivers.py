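"""Driving-force stage: collinearity screening, VIF and OLS fits.

Candidate drivers are first screened pairwise on Pearson correlation
(|r| >= 0.75 eliminates one member of the pair), then checked with
variance-inflation factors (VIF_j = 1/(1 - R2_j), flagged against 5),
and finally each response is regressed on the kept set by ordinary least
squares with two-sided t tests and significance stars at the 0.1 / 0.05 /
0.01 levels.

The elimination rule is deterministic: offending pairs are visited in
descending |r|; within a pair the variable with the larger mean |r|
against all other remaining candidates is dropped, exact ties dropping
the later one in panel column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

RESPONSES = ("Y", "Y1", "Y2", "Y3", "Y4")


def _stars(p: float) -> str:
    if p <= 0.01:
        return "***"
    if p <= 0.05:
        return "**"
    if p <= 0.1:
        return "*"
    return ""


@dataclass
class ScreeningResult:
    kept: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)  # (var, reason, statistic)

    @property
    def dropped_names(self) -> list[str]:
        return [v for v, _, _ in self.dropped]


def pearson_screen(
    panel: pd.DataFrame,
    candidates: list[str],
    threshold: float = 0.75,
) -> ScreeningResult:
    """Greedy pairwise elimination until no kept pair has |r| >= threshold."""
    X = panel[candidates].astype(float)
    if len(X) < 3:
        raise ValueError("need at least 3 rows for correlation screening")
    zero_var = [c for c in candidates if X[c].std(ddof=0) == 0]
    if zero_var:
        raise ValueError(f"constant column(s) {zero_var} have zero variance")

    kept = list(candidates)
    dropped: list[tuple[str, str, float]] = []
    while True:
        corr = X[kept].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        peak = corr.to_numpy().max() if len(kept) > 1 else 0.0
        if peak < threshold:
            break
        # worst offending pair, first in column order on ties
        i, j = np.unravel_index(np.argmax(corr.to_numpy()), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        others_a = [v for v in kept if v != a and v != b]
        mean_a = corr.loc[a, others_a].mean() if others_a else 0.0
        mean_b = corr.loc[b, others_a].mean() if others_a else 0.0
        if mean_a > mean_b:
            victim = a
        elif mean_b > mean_a:
            victim = b
        else:  # exact tie: keep the earlier candidate
            victim = max(a, b, key=candidates.index)
        kept.remove(victim)
        dropped.append((victim, "pairwise_r", float(peak)))
    return ScreeningResult(kept=kept, dropped=dropped)


def vif(panel: pd.DataFrame, variables: list[str]) -> pd.Series:
    """Variance-inflation factor of each variable against the others.

    Perfectly collinear variables get +inf rather than raising.
    """
    X = panel[variables].astype(float)
    if len(X) <= len(variables) + 1:
        raise ValueError("need more rows than variables + 1 for VIF")
    out = {}
    for var in variables:
        others = [v for v in variables if v != var]
        if not others:
            out[var] = 1.0
            continue
        design = sm.add_constant(X[others])
        r2 = sm.OLS(X[var], design).fit().rsquared
        out[var] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class RegressionResult:
    """One OLS fit with its significance report."""

    response: str
    intercept: float
    coefficients: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    stars: pd.Series
    intercept_t: float
    intercept_p: float
    r_squared: float
    n: int
    fitted: pd.Series
    residuals: pd.Series

    def report_column(self) -> pd.Series:
        """Coefficients with stars and t in parentheses, table style."""
        rows = {}
        for var in self.coefficients.index:
            rows[var] = (
                f"{self.coefficients[var]:.4f}{self.stars[var]} ({self.tvalues[var]:.2f})"
            )
        rows["_cons"] = f"{self.intercept:.4f}{_stars(self.intercept_p)} ({self.intercept_t:.2f})"
        rows["N"] = str(self.n)
        rows["R2"] = f"{self.r_squared:.4f}"
        return pd.Series(rows, name=self.response)


def fit_ols(panel: pd.DataFrame, response: str, variables: list[str]) -> RegressionResult:
    """Least-squares fit of one response on the kept variables."""
    y = panel[response].astype(float)
    X = sm.add_constant(panel[list(variables)].astype(float))
    if len(panel) <= len(variables) + 1:
        raise ValueError("need n > number of variables + 1")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix; screen collinear variables first")
    res = sm.OLS(y, X).fit()
    coef = res.params.drop("const")
    pvals = res.pvalues.drop("const")
    return RegressionResult(
        response=response,
        intercept=float(res.params["const"]),
        coefficients=coef,
        tvalues=res.tvalues.drop("const"),
        pvalues=pvals,
        stars=pvals.map(_stars),
        intercept_t=float(res.tvalues["const"]),
        intercept_p=float(res.pvalues["const"]),
        r_squared=float(res.rsquared),
        n=int(res.nobs),
        fitted=pd.Series(res.fittedvalues, index=panel.index),
        residuals=pd.Series(res.resid, index=panel.index),
    )


class DriverRegression(BaseEstimator, RegressorMixin):
    """Screened OLS driver model as a scikit-learn estimator.

    ``fit(X, y)`` screens the columns of ``X`` pairwise at
    ``r_threshold``, records VIFs of the kept set against
    ``vif_threshold``, and fits OLS on the survivors. ``variables`` forces
    a manual kept set and skips screening.
    """

    def __init__(self, r_threshold: float = 0.75, vif_threshold: float = 5.0,
                 variables: list[str] | None = None):
        self.r_threshold = r_threshold
        self.vif_threshold = vif_threshold
        self.variables = variables

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = pd.Series(y, index=X.index, name=getattr(y, "name", None) or "y")
        if self.variables is not None:
            self.screening_ = ScreeningResult(kept=list(self.variables))
        else:
            self.screening_ = pearson_screen(X, list(X.columns), self.r_threshold)
        self.kept_ = list(self.screening_.kept)
        self.vif_ = vif(X, self.kept_)
        self.vif_ok_ = bool((self.vif_ < self.vif_threshold).all())
        frame = X.copy()
        frame[y.name] = y
        self.result_ = fit_ols(frame, y.name, self.kept_)
        self.coef_ = self.result_.coefficients.to_numpy()
        self.intercept_ = self.result_.intercept
        return self

    def predict(self, X: pd.DataFrame):
        X = pd.DataFrame(X)
        return self.intercept_ + X[self.kept_].to_numpy() @ self.coef_


@dataclass
class DriverReport:
    screening: ScreeningResult
    vif: pd.Series
    fits: dict[str, RegressionResult]
    table: pd.DataFrame  # report in published layout: one column per response


def driver_pipeline(
    panel: pd.DataFrame,
    responses: list[str] | tuple[str, ...] = RESPONSES,
    candidates: list[str] | None = None,
    r_threshold: float = 0.75,
    vif_threshold: float = 5.0,
    kept_override: list[str] | None = None,
) -> DriverReport:
    """Screen once, then fit every response on the common kept set."""
    if candidates is None:
        candidates = [c for c in panel.columns if c.startswith("X")]
    if kept_override is not None:
        screening = ScreeningResult(kept=list(kept_override))
    else:
        screening = pearson_screen(panel, candidates, r_threshold)
    vifs = vif(panel, screening.kept)
    fits = {resp: fit_ols(panel, resp, screening.kept) for resp in responses}
    table = pd.DataFrame({resp: fit.report_column() for resp, fit in fits.items()})
    return DriverReport(screening=screening, vif=vifs, fits=fits, table=table)
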