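"""Crop-demand projection from GDP.

Per-capita caloric demand in three diet components (crop, animal, empty) is
modeled as log-linear in GDP per capita, demand = α + β·ln(GDP), recalibrated
by least squares on historical (GDP, demand) pairs. Animal calories convert to
crop-equivalents via feed-meat conversion rates; national demand is per-capita
crop-equivalent demand × population × 365, split across the five
self-sufficiency categories (cereals — pooling rice, maize and wheat —
soybean, peanut, potato, rapeseed) by a configurable share vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cropswitch.cfts import DEMAND_CATEGORIES

DIET_COMPONENTS = ("crop", "animal", "empty")

#: default split of crop-equivalent caloric demand across the five categories
DEFAULT_CATEGORY_SHARES = {
    "cereals": 0.75,
    "soybean": 0.12,
    "peanut": 0.04,
    "potato": 0.06,
    "rapeseed": 0.03,
}


@dataclass
class FeedConversionTable:
    """Crop kcal required per animal kcal, by animal-product class.

    ``classes`` maps class name -> (share of animal calories, conversion rate).
    Shares must sum to 1 and every rate must be >= 1 (feed conversion cannot
    create calories).
    """

    classes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "dairy_eggs": (0.35, 4.0),
            "pork": (0.35, 6.0),
            "poultry": (0.10, 4.0),
            "ruminant_meat": (0.10, 25.0),
            "seafood": (0.10, 3.0),
        }
    )

    def __post_init__(self) -> None:
        shares = np.array([s for s, _ in self.classes.values()])
        rates = np.array([r for _, r in self.classes.values()])
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError("animal-class shares must sum to 1")
        if (rates < 1.0).any():
            raise ValueError("feed conversion rates must be >= 1")

    @property
    def effective_rate(self) -> float:
        """Share-weighted mean crop-kcal per animal-kcal."""
        return float(sum(s * r for s, r in self.classes.values()))


@dataclass
class DemandModel:
    """Fitted log-linear per-capita demand model per diet component.

    ``params`` maps component -> (alpha, beta) of demand = α + β·ln(GDP)
    [kcal/person/day]; ``diagnostics`` maps component -> (mre, r2).
    """

    params: dict[str, tuple[float, float]]
    diagnostics: dict[str, tuple[float, float]]


@dataclass
class DemandSet:
    """National demand by self-sufficiency category for one time step."""

    year: int
    by_category: dict[str, float]  # kcal/yr, keys = DEMAND_CATEGORIES
    per_capita: dict[str, float]  # kcal/person/day per diet component

    def as_array(self) -> np.ndarray:
        return np.array([self.by_category[c] for c in DEMAND_CATEGORIES])


def _mre(pred: np.ndarray, obs: np.ndarray) -> float:
    """Normalized mean absolute error Σ|pred−obs| / Σ|obs| (robust to zero obs)."""
    denom = np.abs(obs).sum()
    if denom == 0:
        return 0.0 if np.abs(pred - obs).sum() == 0 else np.inf
    return float(np.abs(pred - obs).sum() / denom)


def _r2(pred: np.ndarray, obs: np.ndarray) -> float:
    ss_tot = ((obs - obs.mean()) ** 2).sum()
    if ss_tot == 0:
        return 1.0
    return float(1.0 - ((pred - obs) ** 2).sum() / ss_tot)


def fit_demand_model(
    gdp_series: np.ndarray, demand_series: dict[str, np.ndarray]
) -> DemandModel:
    """Least-squares fit of demand = α + β·ln(GDP) per diet component.

    Requires at least 3 points per component and strictly positive GDP.
    """
    gdp = np.asarray(gdp_series, dtype=float)
    if (gdp <= 0).any():
        raise ValueError("GDP values must be positive")
    lng = np.log(gdp)
    X = np.column_stack([np.ones_like(lng), lng])
    params: dict[str, tuple[float, float]] = {}
    diags: dict[str, tuple[float, float]] = {}
    for comp, dem in demand_series.items():
        d = np.asarray(dem, dtype=float)
        if len(d) != len(gdp) or len(d) < 3:
            raise ValueError("need >= 3 (GDP, demand) points per component")
        coef, *_ = np.linalg.lstsq(X, d, rcond=None)
        pred = X @ coef
        params[comp] = (float(coef[0]), float(coef[1]))
        diags[comp] = (_mre(pred, d), _r2(pred, d))
    return DemandModel(params=params, diagnostics=diags)


def per_capita_demand(model: DemandModel, gdp: float) -> dict[str, float]:
    """Evaluate α + β·ln(GDP) per component, floored at zero (kcal/person/day)."""
    if gdp <= 0:
        raise ValueError("GDP must be positive")
    lng = np.log(gdp)
    return {
        comp: max(0.0, a + b * lng) for comp, (a, b) in model.params.items()
    }


def national_crop_demand(
    percap: dict[str, float],
    conversions: FeedConversionTable,
    population: float,
    crop_category_shares: dict[str, float] | None = None,
    *,
    include_empty: bool = False,
    year: int = 0,
) -> DemandSet:
    """National crop-equivalent demand by self-sufficiency category.

    Animal calories are multiplied by feed conversion rates and added to crop
    calories; empty calories (fats/sugars/alcohol) are excluded by default as
    they are not supplied by the optimized staple crops. The total is scaled by
    population × 365 and split across the five categories.
    """
    if population < 0:
        raise ValueError("population must be nonnegative")
    shares = dict(crop_category_shares or DEFAULT_CATEGORY_SHARES)
    if set(shares) != set(DEMAND_CATEGORIES):
        raise ValueError(f"shares must cover exactly {DEMAND_CATEGORIES}")
    if abs(sum(shares.values()) - 1.0) > 1e-9:
        raise ValueError("category shares must sum to 1")

    crop_eq = percap.get("crop", 0.0) + conversions.effective_rate * percap.get(
        "animal", 0.0
    )
    if include_empty:
        crop_eq += percap.get("empty", 0.0)
    annual_total = crop_eq * population * 365.0
    by_cat = {c: annual_total * shares[c] for c in DEMAND_CATEGORIES}
    return DemandSet(year=year, by_category=by_cat, per_capita=dict(percap))
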