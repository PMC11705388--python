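"""Fertilization dose–response analysis.

A fixed allocation is re-evaluated across national fertilizer totals (default
0–100 Mt N, step 5) under an unaltered spatial application pattern; the
resulting national CP and LN intensities (per sown hectare) are distilled
into a logistic curve

    P(t) = K·P0·e^{rt} / (K + P0·(e^{rt} − 1))

for CP intensity and a cubic polynomial LN(t) = a0·t³ + a1·t² + a2·t + a3 for
LN intensity, with t the mean application rate (kg N/ha). The marginal return
P′(t) = r·P(t)·(1 − P(t)/K) partitions the rate axis into low/medium/high
fertilization-priority stages; the high stage — a single interval because P′
is unimodal — is the sustainable fertilization boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from cropswitch.synthetic import (
    DEFAULT_SOIL_N_BASELINE,
    Allocation,
    Region,
    gen_suitability,
)

#: default sweep levels, Mt N
DEFAULT_LEVELS_MT = tuple(np.arange(0.0, 101.0, 5.0))
#: default priority thresholds, kcal per kg N
THETA_LOW = 5e3
THETA_HIGH = 3e4

KG_PER_MT = 1e9


def _mre(pred: np.ndarray, obs: np.ndarray) -> float:
    denom = np.abs(obs).sum()
    if denom == 0:
        return 0.0 if np.abs(pred - obs).sum() == 0 else np.inf
    return float(np.abs(pred - obs).sum() / denom)


def _r2(pred: np.ndarray, obs: np.ndarray) -> float:
    ss_tot = ((obs - obs.mean()) ** 2).sum()
    if ss_tot == 0:
        return 1.0
    return float(1.0 - ((pred - obs) ** 2).sum() / ss_tot)


@dataclass
class LogisticCurve:
    """Fitted logistic CP-intensity response with diagnostics."""

    p0: float  # initial CP intensity without mineral fertilizer, kcal/ha
    k: float  # maximum fertilization-induced CP intensity, kcal/ha
    r: float  # response rate, per kg N/ha
    r2: float = np.nan
    mre: float = np.nan

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        e = np.exp(np.clip(self.r * np.asarray(t, dtype=float), None, 500.0))
        return self.k * self.p0 * e / (self.k + self.p0 * (e - 1.0))

    def derivative(self, t: np.ndarray | float):
        """Marginal CP-intensity return P′(t) = r·P·(1 − P/K), kcal per kg N."""
        p = self(t)
        return self.r * p * (1.0 - p / self.k)

    @property
    def max_slope(self) -> float:
        """Peak marginal return r·K/4 (at the inflection point)."""
        return self.r * self.k / 4.0

    @property
    def inflection(self) -> float:
        """Rate at which P = K/2; 0 if the curve starts past its inflection."""
        if self.p0 >= self.k / 2.0:
            return 0.0
        return float(np.log((self.k - self.p0) / self.p0) / self.r)


@dataclass
class CubicCurve:
    """Fitted cubic LN-intensity response, LN(t) = a0·t³ + a1·t² + a2·t + a3."""

    a0: float
    a1: float
    a2: float
    a3: float
    r2: float = np.nan
    mre: float = np.nan

    def __call__(self, t: np.ndarray | float):
        t = np.asarray(t, dtype=float)
        return ((self.a0 * t + self.a1) * t + self.a2) * t + self.a3


@dataclass
class PriorityPartition:
    """Low/medium/high fertilization-priority stages on the rate axis.

    ``intervals`` maps each stage label to a list of (lo, hi) rate intervals;
    ``sustainable`` is the high-priority interval (the sustainable
    fertilization boundary), or None when the high stage is empty.
    """

    theta_low: float
    theta_high: float
    intervals: dict[str, list[tuple[float, float]]]
    sustainable: tuple[float, float] | None

    @property
    def empty(self) -> bool:
        return self.sustainable is None


def sweep_fertilization(
    alloc: Allocation,
    region: Region,
    cfts: pd.DataFrame,
    levels_mt=DEFAULT_LEVELS_MT,
    spatial_pattern: np.ndarray | None = None,
    *,
    soil_n_baseline: float = DEFAULT_SOIL_N_BASELINE,
    climate_shift: float = 0.0,
) -> pd.DataFrame:
    """Evaluate national CP/LN intensity across total fertilizer levels.

    The fixed spatial pattern (per-county share of the national total;
    default proportional to county area, i.e. a spatially uniform rate) is
    scaled multiplicatively to hit each level; suitability is regenerated at
    the implied per-county rates with noise off. Intensities are national
    totals divided by total sown area. Returns a DataFrame with columns
    total_mt, rate_kg_ha, cp_intensity, ln_intensity.
    """
    levels = np.asarray(levels_mt, dtype=float)
    if (levels < 0).any():
        raise ValueError("levels must be nonnegative")
    if (np.diff(levels) <= 0).any():
        raise ValueError("levels must be strictly ascending")
    areas = region.areas
    total_area = areas.sum()
    if spatial_pattern is None:
        pattern = areas / total_area
    else:
        pattern = np.asarray(spatial_pattern, dtype=float)
        if abs(pattern.sum() - 1.0) > 1e-9:
            raise ValueError("spatial pattern shares must sum to 1")
    sown = alloc.row_sums().sum()

    rows = []
    cal = cfts["calories_kcal_t"].to_numpy()[None, :]
    for lv in levels:
        rates = lv * KG_PER_MT * pattern / areas
        suit = gen_suitability(
            region,
            cfts,
            rates,
            climate_shift=climate_shift,
            sigma_yield=0.0,
            sigma_water=0.0,
            soil_n_baseline=soil_n_baseline,
        )
        cp = float((alloc.areas_ha * suit.yield_t_ha * cal).sum())
        ln = float((alloc.areas_ha * suit.leach_kg_ha).sum())
        rows.append(
            {
                "total_mt": lv,
                "rate_kg_ha": lv * KG_PER_MT / sown,
                "cp_intensity": cp / sown,
                "ln_intensity": ln / sown,
            }
        )
    return pd.DataFrame(rows)


def fit_logistic(samples: pd.DataFrame) -> LogisticCurve:
    """Nonlinear least-squares fit of the logistic CP-intensity response.

    Initialization: P0 from the first sample, K at 1.05 × the sample maximum,
    r slope-matched at the midpoint of the rate range — robust for saturating
    data. Raises RuntimeError with diagnostics on failed convergence.
    """
    t = samples["rate_kg_ha"].to_numpy(dtype=float)
    y = samples["cp_intensity"].to_numpy(dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 sweep samples")
    if np.ptp(t) == 0:
        raise ValueError("degenerate rate grid")

    p0_init = max(y[0], 1e-12)
    k_init = 1.05 * y.max()
    mid = len(t) // 2
    slope = np.gradient(y, t)[mid]
    p_mid = min(max(y[mid], 1e-12), 0.999 * k_init)
    r_init = max(slope / (p_mid * (1.0 - p_mid / k_init)), 1e-6)

    def f(tt, p0, k, r):
        e = np.exp(np.clip(r * tt, None, 500.0))
        return k * p0 * e / (k + p0 * (e - 1.0))

    try:
        popt, _ = curve_fit(
            f,
            t,
            y,
            p0=[p0_init, k_init, r_init],
            bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # convergence failure
        raise RuntimeError(
            f"logistic fit failed to converge (init P0={p0_init:.4g}, "
            f"K={k_init:.4g}, r={r_init:.4g}): {exc}"
        ) from exc
    pred = f(t, *popt)
    return LogisticCurve(
        p0=float(popt[0]),
        k=float(popt[1]),
        r=float(popt[2]),
        r2=_r2(pred, y),
        mre=_mre(pred, y),
    )


def fit_cubic(samples: pd.DataFrame) -> CubicCurve:
    """Ordinary least squares of LN intensity on {t³, t², t, 1}."""
    t = samples["rate_kg_ha"].to_numpy(dtype=float)
    y = samples["ln_intensity"].to_numpy(dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 sweep samples")
    X = np.vander(t, 4)  # columns t³, t², t, 1
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design (degenerate rate grid)")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coef
    return CubicCurve(
        a0=float(coef[0]),
        a1=float(coef[1]),
        a2=float(coef[2]),
        a3=float(coef[3]),
        r2=_r2(pred, y),
        mre=_mre(pred, y),
    )


def _crossings(
    curve: LogisticCurve, theta: float, lo: float, hi: float
) -> list[float]:
    """Rates in (lo, hi) where P′(t) = theta, via bracketed root solves.

    P′ is unimodal with its maximum at the inflection, so there is at most one
    crossing on each side of it.
    """
    g = lambda t: curve.derivative(t) - theta
    tstar = min(max(curve.inflection, lo), hi)
    roots = []
    for a, b in ((lo, tstar), (tstar, hi)):
        if b - a <= 0:
            continue
        ga, gb = g(a), g(b)
        if ga == 0.0:
            roots.append(a)
        elif ga * gb < 0:
            roots.append(brentq(g, a, b, xtol=1e-10 * max(1.0, hi)))
        elif gb == 0.0:
            roots.append(b)
    return sorted(set(roots))


def partition_priorities(
    curve: LogisticCurve,
    theta_low: float = THETA_LOW,
    theta_high: float = THETA_HIGH,
    rate_range: tuple[float, float] | None = None,
) -> PriorityPartition:
    """Partition the rate axis into low/medium/high priority stages.

    Stages are defined on the marginal return: P′ < θ_low is low priority,
    θ_low ≤ P′ ≤ θ_high medium, P′ > θ_high high. The high stage, when
    non-empty, is a single interval [t_lo, t_hi] (boundary included) returned
    as the sustainable fertilization boundary.
    """
    if theta_low >= theta_high:
        raise ValueError("theta_low must be < theta_high")
    lo, hi = rate_range if rate_range is not None else (0.0, 4.0 * curve.inflection or 1000.0)
    if hi <= lo:
        raise ValueError("empty rate range")

    def stage(t: float) -> str:
        d = curve.derivative(t)
        if d > theta_high:
            return "high"
        if d < theta_low:
            return "low"
        return "medium"

    cuts = sorted(
        set(
            [lo, hi]
            + _crossings(curve, theta_low, lo, hi)
            + _crossings(curve, theta_high, lo, hi)
        )
    )
    intervals: dict[str, list[tuple[float, float]]] = {
        "low": [],
        "medium": [],
        "high": [],
    }
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b - a <= 0:
            continue
        intervals[stage(0.5 * (a + b))].append((a, b))

    if theta_high > curve.max_slope:
        sustainable = None
    elif theta_high == curve.max_slope:
        t = min(max(curve.inflection, lo), hi)
        sustainable = (t, t)
        intervals["high"] = [(t, t)]
    else:
        high = intervals["high"]
        if not high:
            sustainable = None
        else:
            sustainable = (high[0][0], high[-1][1])
            intervals["high"] = [sustainable]
    return PriorityPartition(
        theta_low=theta_low,
        theta_high=theta_high,
        intervals=intervals,
        sustainable=sustainable,
    )


@dataclass
class GapReport:
    """Position of a baseline fertilization rate against a sustainable boundary."""

    classification: str  # below | within | above
    distance: float  # signed kg N/ha to the nearest boundary (0 when within)
    boundary: tuple[float, float]


def fertilization_gap(partition: PriorityPartition, baseline_rate: float) -> GapReport:
    """Classify a baseline rate against the sustainable boundary [t_lo, t_hi]."""
    if partition.sustainable is None:
        raise ValueError("partition has an empty sustainable boundary")
    t_lo, t_hi = partition.sustainable
    if baseline_rate < t_lo:
        return GapReport("below", baseline_rate - t_lo, (t_lo, t_hi))
    if baseline_rate > t_hi:
        return GapReport("above", baseline_rate - t_hi, (t_lo, t_hi))
    return GapReport("within", 0.0, (t_lo, t_hi))
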