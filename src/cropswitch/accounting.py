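"""Benefit accounting: optimized vs baseline runs, driver attribution, tradeoffs.

Benefits are percent differences of national CP/LN/IWU between an optimized
and a baseline scenario run; counties are classified into the eight sign
combinations of (ΔCP, ΔLN, ΔIWU), with strictly-positive deltas on the "+"
side and zeros on the "−" side, so the co-benefit class (+, −, −) requires a
strict CP gain. Climate and fertilizer-management contributions to CP come
from controlled-scenario differencing: holding climate constant isolates the
climate effect, additionally holding fertilization constant isolates the
fertilizer effect, and the two add exactly to the combined effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cropswitch.cfts import CROP_GROUPS
from cropswitch.optimize import OptimizationProblem, OptimizerConfig, evolve
from cropswitch.synthetic import Allocation, SuitabilitySurface

DIMENSIONS = ("cp", "ln", "iwu")

#: default intensity thresholds for the high-intensity county shares
INTENSITY_THRESHOLDS = {"cp": 20e6, "ln": 75.0, "iwu": 90.0}

#: labels for the 8 sign combinations (cp_up, ln_up, iwu_up); "+" iff delta > 0
TRADEOFF_LABELS = {
    (True, False, False): "co-benefit",
    (True, False, True): "CP and LN benefit with IWU tradeoff",
    (True, True, False): "CP and IWU benefit with LN tradeoff",
    (True, True, True): "CP benefit with LN and IWU tradeoff",
    (False, False, False): "neutral-nonpositive",
    (False, False, True): "LN benefit with CP and IWU tradeoff",
    (False, True, False): "water-saving with CP and LN tradeoff",
    (False, True, True): "all-dimension loss",
}


@dataclass
class ScenarioRun:
    """Per-county, per-crop CP/LN/IWU of one scenario at one time slice.

    ``table`` columns: county_id, crop, cp_kcal, ln_kg, iwu_mm_ha.
    """

    label: str
    table: pd.DataFrame
    year: int = 0

    def county_totals(self) -> pd.DataFrame:
        return (
            self.table.groupby("county_id")[["cp_kcal", "ln_kg", "iwu_mm_ha"]]
            .sum()
            .sort_index()
        )

    def national(self) -> dict[str, float]:
        t = self.table[["cp_kcal", "ln_kg", "iwu_mm_ha"]].sum()
        return {"cp": float(t["cp_kcal"]), "ln": float(t["ln_kg"]), "iwu": float(t["iwu_mm_ha"])}


def scenario_from_allocation(
    alloc: Allocation,
    suit: SuitabilitySurface,
    cfts: pd.DataFrame,
    label: str,
    year: int = 0,
) -> ScenarioRun:
    """Build a ScenarioRun table from an allocation and a suitability surface."""
    n, J = alloc.areas_ha.shape
    cal = cfts["calories_kcal_t"].to_numpy()
    rows = {
        "county_id": np.repeat(np.arange(n), J),
        "crop": np.tile(cfts["crop_group"].to_numpy(), n),
        "cp_kcal": (alloc.areas_ha * suit.yield_t_ha * cal[None, :]).ravel(),
        "ln_kg": (alloc.areas_ha * suit.leach_kg_ha).ravel(),
        "iwu_mm_ha": (alloc.areas_ha * suit.irrigation_mm).ravel(),
    }
    table = (
        pd.DataFrame(rows)
        .groupby(["county_id", "crop"], as_index=False)
        .sum()
    )
    return ScenarioRun(label=label, table=table, year=year)


@dataclass
class BenefitReport:
    """National and per-county differences between optimized and baseline."""

    national_pct: dict[str, float]  # ΔCP, ΔLN, ΔIWU in % of baseline
    per_county: pd.DataFrame  # county_id, d_cp, d_ln, d_iwu (absolute), tradeoff class
    class_counts: dict[str, int]


def _check_same_counties(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if not a.index.equals(b.index):
        raise ValueError("scenario runs cover different county sets")


def benefit_report(optimized: ScenarioRun, baseline: ScenarioRun) -> BenefitReport:
    """Δ% = (optimized − baseline) / baseline × 100 per dimension, plus tradeoff classes."""
    opt_nat, base_nat = optimized.national(), baseline.national()
    if any(base_nat[d] <= 0 for d in DIMENSIONS):
        raise ValueError("baseline national totals must be positive")
    national_pct = {
        d: (opt_nat[d] - base_nat[d]) / base_nat[d] * 100.0 for d in DIMENSIONS
    }
    opt_c, base_c = optimized.county_totals(), baseline.county_totals()
    _check_same_counties(opt_c, base_c)
    deltas = opt_c - base_c
    per_county = pd.DataFrame(
        {
            "county_id": deltas.index,
            "d_cp": deltas["cp_kcal"].to_numpy(),
            "d_ln": deltas["ln_kg"].to_numpy(),
            "d_iwu": deltas["iwu_mm_ha"].to_numpy(),
        }
    )
    per_county["tradeoff"] = classify_tradeoffs(
        per_county["d_cp"].to_numpy(),
        per_county["d_ln"].to_numpy(),
        per_county["d_iwu"].to_numpy(),
    )
    counts = per_county["tradeoff"].value_counts().to_dict()
    return BenefitReport(
        national_pct=national_pct, per_county=per_county, class_counts=counts
    )


def classify_tradeoffs(
    d_cp: np.ndarray, d_ln: np.ndarray, d_iwu: np.ndarray
) -> np.ndarray:
    """Sign-triple classification of per-county deltas into the 8 classes.

    A dimension is on the "+" side iff its delta is strictly positive; exact
    zeros fall on the "−" side, so (0, 0, 0) lands in the neutral-nonpositive
    class and a co-benefit requires a strict CP increase.
    """
    d_cp, d_ln, d_iwu = map(np.atleast_1d, (d_cp, d_ln, d_iwu))
    out = np.empty(len(d_cp), dtype=object)
    for i in range(len(d_cp)):
        key = (bool(d_cp[i] > 0), bool(d_ln[i] > 0), bool(d_iwu[i] > 0))
        out[i] = TRADEOFF_LABELS[key]
    return out


@dataclass
class DriverAttribution:
    """Climate vs fertilizer-management contributions to CP change."""

    climate: pd.DataFrame  # baseline − constant-climate, per county
    fertilizer: pd.DataFrame  # constant-climate − constant-both
    combined: pd.DataFrame  # baseline − constant-both
    national: dict[str, float] = field(default_factory=dict)


def attribute_drivers(
    baseline: ScenarioRun, const_climate: ScenarioRun, const_both: ScenarioRun
) -> DriverAttribution:
    """Controlled-scenario differencing of CP drivers; effects add exactly."""
    b, cc, cb = (
        baseline.county_totals(),
        const_climate.county_totals(),
        const_both.county_totals(),
    )
    _check_same_counties(b, cc)
    _check_same_counties(b, cb)
    climate = b - cc
    fertilizer = cc - cb
    combined = climate + fertilizer  # telescopes to baseline − constant-both
    national = {
        "climate": float(climate["cp_kcal"].sum()),
        "fertilizer": float(fertilizer["cp_kcal"].sum()),
        "combined": float(combined["cp_kcal"].sum()),
    }
    return DriverAttribution(
        climate=climate, fertilizer=fertilizer, combined=combined, national=national
    )


def intensity_distribution(
    per_county_intensity: np.ndarray, threshold: float, bins: int = 20
) -> tuple[float, np.ndarray, np.ndarray]:
    """Share of counties strictly above a threshold plus a fixed-bin histogram."""
    v = np.asarray(per_county_intensity, dtype=float)
    if v.size == 0:
        raise ValueError("empty intensity vector")
    if (v < 0).any():
        raise ValueError("intensities must be nonnegative")
    share = float((v > threshold).mean())
    hist, edges = np.histogram(v, bins=bins)
    return share, hist, edges


def nitrogen_use_efficiency(harvested_n: float, total_n_input: float) -> float:
    """NUE = harvested nitrogen / total nitrogen input."""
    if total_n_input <= 0:
        raise ValueError("total nitrogen input must be positive")
    return harvested_n / total_n_input


def penalty_sensitivity(
    problem: OptimizationProblem,
    config: OptimizerConfig,
    factor_grid: list[tuple[float, float]],
) -> pd.DataFrame:
    """Rerun the optimizer across penalty-weight multipliers.

    Each grid point (m_sf, m_cp) exponentiates p_sf by m_sf and scales p_cp by
    m_cp (1, 1 is the reference). The report gives, per grid point, the
    maximum absolute change (percentage points) in national crop-area shares,
    averaged over the returned front, versus the reference run.
    """

    def front_shares(m_sf: float, m_cp: float) -> np.ndarray:
        from dataclasses import replace

        pen = replace(config.penalties, sf_weight=m_sf, cp_weight=m_cp)
        cfg = replace(config, penalties=pen)
        sols = evolve(problem, cfg)
        G = np.array(
            [
                [1.0 if g == grp else 0.0 for grp in CROP_GROUPS]
                for g in problem.cfts["crop_group"]
            ]
        )
        total = problem.region.total_area
        shares = np.array(
            [(sol[0].areas_ha @ G).sum(axis=0) / total for sol in sols]
        )
        return shares.mean(axis=0)

    ref = front_shares(1.0, 1.0)
    rows = []
    for m_sf, m_cp in factor_grid:
        shares = ref if (m_sf == 1.0 and m_cp == 1.0) else front_shares(m_sf, m_cp)
        rows.append(
            {
                "m_sf": m_sf,
                "m_cp": m_cp,
                "max_abs_change_pct": float(np.abs(shares - ref).max() * 100.0),
            }
        )
    return pd.DataFrame(rows)
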