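"""Seeded generators emulating the study's data structures.

Three generators produce, with full determinism per seed (NumPy PCG64):

* area panels — per-region compositional land-cover shares with per-type
  annual drift (urban growth, paddy decline), renormalized and scaled to
  a fixed regional total so areas conserve the region's land endowment;
* yield panels — district food yields around regional means with
  multiplicative noise, feeding the spatiotemporal factor;
* driver panels — 19 candidate predictors with engineered collinearity
  blocks (satellite variables share a latent factor with an anchor, so
  the target pairwise correlation is analytic: r = 1/(1 + sigma^2) for
  unit-loading satellites) and responses that are known linear
  combinations of the anchors plus Gaussian noise, with the ground truth
  returned alongside.

Defaults mirror the study conditions: 13 districts, the six survey years
1996-2018, a citywide land endowment of 856,915 hm2 split evenly, initial
shares equal to the observed 1996 composition, and drift signs/magnitudes
of the observed per-type dynamic indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogs import LULC_TYPES
from .io import validate_area_panel

logger = logging.getLogger(__name__)

#: Observed 1996 citywide composition (shares of total area).
DEFAULT_INITIAL_SHARES: dict[str, float] = {
    "paddy_field": 0.2712, "dry_land": 0.2239, "woodland": 0.0905,
    "grassland": 0.0081, "river_lake": 0.1220, "natural_wetland": 0.0285,
    "manmade_wetland": 0.0819, "builtup": 0.1493, "unused": 0.0246,
}
#: Annual multiplicative drift per type (fraction/yr), signs and rough
#: magnitudes of the observed 1996-2018 dynamic indices.
DEFAULT_DRIFT: dict[str, float] = {
    "paddy_field": -0.018, "dry_land": -0.007, "woodland": 0.015,
    "grassland": -0.15, "river_lake": 0.002, "natural_wetland": -0.014,
    "manmade_wetland": 0.028, "builtup": 0.029, "unused": -0.037,
}

STUDY_YEARS = (1996, 2000, 2005, 2010, 2015, 2018)

#: The study's retained driver set acts as the anchor variables.
DEFAULT_ANCHORS = ("X1", "X4", "X9", "X15", "X16", "X18", "X19")
#: True response coefficients on the anchors (signs as in the fitted models).
DEFAULT_ALPHA: dict[str, float] = {
    "X4": -0.45, "X15": 6.63, "X16": 0.0003, "X18": 0.23,
}
DEFAULT_BETA = -245.0


@dataclass
class SyntheticConfig:
    """Shared configuration for the three generators."""

    seed: int = 0
    n_regions: int = 13
    years: tuple[int, ...] = STUDY_YEARS
    total_area: float = 856_915.0 / 13          # hm2 per region
    initial_shares: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INITIAL_SHARES))
    drift: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    share_noise_sd: float = 0.02                # lognormal sd on shares
    yield_means: tuple[float, ...] | None = None  # kg/hm2 per region; default drawn 4000-7000
    yield_noise_sd: float = 0.08
    # driver spec
    anchors: tuple[str, ...] = DEFAULT_ANCHORS
    n_predictors: int = 19
    target_r: float = 0.9                       # satellite-anchor correlation
    alpha: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    beta: float = DEFAULT_BETA
    response_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        total = sum(self.initial_shares.values())
        if any(v < 0 for v in self.initial_shares.values()) or total <= 0:
            raise ValueError("initial shares must be non-negative with positive sum")
        self.initial_shares = {k: v / total for k, v in self.initial_shares.items()}

    def region_labels(self) -> list[str]:
        return [f"R{i + 1:02d}" for i in range(self.n_regions)]

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


def gen_area_panel(cfg: SyntheticConfig) -> pd.DataFrame:
    """Compositional area panel: shares drift, renormalize, scale to totals."""
    rng = cfg.rng(stream=1)
    types = [t for t in LULC_TYPES if t in cfg.initial_shares]
    rows = []
    base_year = cfg.years[0]
    for region in cfg.region_labels():
        noise = rng.lognormal(mean=0.0, sigma=cfg.share_noise_sd, size=len(types))
        start = np.array([cfg.initial_shares[t] for t in types]) * noise
        start /= start.sum()
        for year in cfg.years:
            dt = year - base_year
            shares = start * np.array([(1.0 + cfg.drift.get(t, 0.0)) ** dt for t in types])
            clipped = np.clip(shares, 0.0, None)
            if (clipped != shares).any():
                logger.info("negative drifted share clipped for region %s year %s", region, year)
            shares = clipped / clipped.sum()
            for t, sh in zip(types, shares):
                rows.append((region, year, t, sh * cfg.total_area))
    panel = pd.DataFrame(rows, columns=["region", "year", "lulc", "area_ha"])
    return validate_area_panel(panel)


def gen_yield_panel(cfg: SyntheticConfig) -> pd.DataFrame:
    """District-year food yields (kg/hm2) with multiplicative noise."""
    rng = cfg.rng(stream=2)
    if cfg.yield_means is not None:
        means = np.asarray(cfg.yield_means, dtype=float)
        if len(means) != cfg.n_regions:
            raise ValueError("yield_means must give one mean per region")
    else:
        means = rng.uniform(4000.0, 7000.0, size=cfg.n_regions)
    rows = []
    for region, mean in zip(cfg.region_labels(), means):
        for year in cfg.years:
            dyph = 0.0
            for _ in range(100):  # bounded retries for positivity
                dyph = mean * (1.0 + rng.normal(0.0, cfg.yield_noise_sd))
                if dyph > 0:
                    break
            else:
                raise RuntimeError("could not draw a positive yield")
            rows.append((region, year, dyph))
    return pd.DataFrame(rows, columns=["region", "year", "dyph"])


@dataclass
class DriverTruth:
    """Ground truth stored alongside a generated driver panel."""

    beta: float
    alpha: dict[str, float]
    noise_sd: float
    anchors: tuple[str, ...]
    blocks: dict[str, str]      # satellite -> anchor it tracks
    target_r: float


def gen_driver_panel(
    cfg: SyntheticConfig,
    esv_summary: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, DriverTruth]:
    """Driver panel with engineered collinearity and known linear responses.

    Anchors are independent standard normals (scaled to plausible units);
    each remaining predictor is a satellite x = f + eps tied to one anchor's
    latent f with eps-variance 1/r - 1, giving pairwise correlation ~= r.
    Responses Y and Y1-Y4 are beta + sum(alpha_i * anchor_i) + noise; Y1-Y4
    use scaled-down copies of the same truth. If ``esv_summary`` (a year ->
    total frame) is given, Y is shifted by the matching yearly totals.
    """
    if cfg.target_r <= 0 or cfg.target_r >= 1:
        raise ValueError("target_r must lie strictly between 0 and 1")
    rng = cfg.rng(stream=3)
    n = cfg.n_regions * len(cfg.years)
    names = [f"X{i + 1}" for i in range(cfg.n_predictors)]
    anchors = [a for a in cfg.anchors if a in names]

    latent = {a: rng.normal(size=n) for a in anchors}
    eps_var = 1.0 / cfg.target_r - 1.0
    data = {}
    blocks: dict[str, str] = {}
    satellites = [v for v in names if v not in anchors]
    for i, v in enumerate(satellites):
        anchor = anchors[i % len(anchors)]
        blocks[v] = anchor
        data[v] = latent[anchor] + rng.normal(0.0, np.sqrt(eps_var), size=n)
    for a in anchors:
        data[a] = latent[a]

    X = pd.DataFrame(data)[names]
    signal = cfg.beta + sum(coef * X[var] for var, coef in cfg.alpha.items())
    noise = rng.normal(0.0, cfg.response_noise_sd, size=n)
    index = pd.MultiIndex.from_product(
        [cfg.region_labels(), cfg.years], names=["region", "year"]
    )
    panel = X.set_axis(index).reset_index()
    panel["Y"] = (signal + noise).to_numpy()
    if esv_summary is not None:
        totals = pd.Series(esv_summary.squeeze())
        panel["Y"] += panel["year"].map(totals).fillna(0.0).to_numpy()
    for i, frac in enumerate((0.08, 0.65, 0.10, 0.04), start=1):
        panel[f"Y{i}"] = frac * signal.to_numpy() + rng.normal(
            0.0, cfg.response_noise_sd * frac, size=n
        )
    truth = DriverTruth(
        beta=cfg.beta, alpha=dict(cfg.alpha), noise_sd=cfg.response_noise_sd,
        anchors=tuple(anchors), blocks=blocks, target_r=cfg.target_r,
    )
    return panel, truth
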