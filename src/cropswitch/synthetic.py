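"""Synthetic agro-ecosystem generator.

Emulates, from seeds alone, the inputs a process-based vegetation model and
external datasets would supply for a national crop-switching study: per-county
agro-ecological suitability (attainable yield, leached nitrogen, irrigation
water demand per CFT, as if that CFT occupied all cropland), baseline
planting-area allocations, and socio-economic trajectories.

Structural choices, not fitted to any dataset:

* yield = Monod response to nitrogen supply × Gaussian climate suitability;
* leached N = convex law l1·f²/(f+l2) in the *applied* rate (zero without
  mineral fertilizer), scaled up in nitrogen-loaded counties;
* irrigation demand linear in the county aridity index;
* county covariates follow an order-1 autoregressive pass over county index so
  that neighboring ids are correlated (a cheap stand-in for spatial
  autocorrelation);
* all noise is multiplicative (1 + ε), ε truncated at −0.9, preserving
  non-negativity without rejection sampling.

Total regional cropland defaults to a fixed national-scale figure (1.28e8 ha)
distributed across however many counties are requested, so a 10-county toy
region carries national-scale areas and national fertilizer totals (Mt N)
convert to realistic per-hectare rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

#: default total regional cropland, ha (national scale)
DEFAULT_TOTAL_AREA_HA = 1.28e8
#: default background soil-N supply used when evaluating response sweeps, kg N/ha
DEFAULT_SOIL_N_BASELINE = 80.0
#: reference national fertilization rate, kg N/ha
BASELINE_FERT_RATE = 305.0


@dataclass
class Region:
    """Counties with covariates plus the grid cells that compose them.

    ``counties`` columns: county_id, area_ha, climate, aridity, n_surplus, tws.
    ``cells`` columns: cell_id, county_id, area_ha.
    """

    counties: pd.DataFrame
    cells: pd.DataFrame

    @property
    def n_counties(self) -> int:
        return len(self.counties)

    @property
    def areas(self) -> np.ndarray:
        """County cropland areas S_i in ha."""
        return self.counties["area_ha"].to_numpy()

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def validate(self) -> None:
        c = self.counties
        if c["county_id"].nunique() != len(c):
            raise ValueError("county ids must be unique")
        if (c["area_ha"] <= 0).any():
            raise ValueError("county areas must be positive")
        if not self.cells["county_id"].isin(c["county_id"]).all():
            raise ValueError("every cell must map to an existing county")
        cell_sum = self.cells.groupby("county_id")["area_ha"].sum()
        cell_sum = cell_sum.reindex(c["county_id"]).to_numpy()
        if np.any(np.abs(cell_sum - self.areas) > 1e-9 * self.areas):
            raise ValueError("cell areas must sum to county area")


@dataclass
class SuitabilitySurface:
    """Per-(county, CFT) suitability: yield, leached N, irrigation intensities.

    Arrays are (n_counties, n_cfts); ``fert_rate`` is the per-county nitrogen
    application rate (kg N/ha) at which the surface was evaluated.
    """

    yield_t_ha: np.ndarray
    leach_kg_ha: np.ndarray
    irrigation_mm: np.ndarray
    fert_rate: np.ndarray

    def validate(self) -> None:
        for a in (self.yield_t_ha, self.leach_kg_ha, self.irrigation_mm):
            if (a < 0).any():
                raise ValueError("suitability values must be nonnegative")
            if a.shape != self.yield_t_ha.shape:
                raise ValueError("inconsistent suitability array shapes")


@dataclass
class Allocation:
    """County × CFT planting areas s_ij (ha), rows on the county area simplex."""

    areas_ha: np.ndarray  # (n_counties, n_cfts)

    def row_sums(self) -> np.ndarray:
        return self.areas_ha.sum(axis=1)

    def fractions(self) -> np.ndarray:
        return self.areas_ha / self.row_sums()[:, None]

    def check_simplex(self, county_areas: np.ndarray, rtol: float = 1e-9) -> None:
        if (self.areas_ha < 0).any():
            raise ValueError("planting areas must be nonnegative")
        dev = np.abs(self.row_sums() - county_areas)
        if np.any(dev > rtol * county_areas):
            raise ValueError("county planting areas must sum to county cropland")


@dataclass
class SocioEconomicTrajectory:
    """GDP per capita and population on a strict 5-year grid."""

    years: np.ndarray
    gdp_per_capita: np.ndarray
    population: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "gdp_per_capita": self.gdp_per_capita,
                "population": self.population,
            }
        )


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Stationary AR(1) sequence with N(0,1) marginals over county index."""
    e = rng.standard_normal(n)
    z = np.empty(n)
    z[0] = e[0]
    scale = np.sqrt(1.0 - rho * rho)
    for k in range(1, n):
        z[k] = rho * z[k - 1] + scale * e[k]
    return z


def gen_region(
    n_counties: int,
    cells_per_county: int,
    seed: int,
    *,
    rho: float = 0.6,
    total_area_ha: float = DEFAULT_TOTAL_AREA_HA,
    area_sigma: float = 0.8,
) -> Region:
    """Generate a synthetic region of counties subdivided into grid cells.

    County covariates (climate coordinate, aridity, nitrogen-surplus and
    terrestrial-water-storage scores) are spatially autocorrelated via an AR(1)
    pass with coefficient ``rho``. Areas are lognormal in shape, normalized so
    the region totals ``total_area_ha`` exactly.
    """
    if n_counties < 1 or cells_per_county < 1:
        raise ValueError("n_counties and cells_per_county must be >= 1")
    rng = np.random.default_rng(seed)

    climate = ndtr(_ar1(rng, n_counties, rho))
    aridity = ndtr(_ar1(rng, n_counties, rho))
    n_surplus = np.exp(0.6 * _ar1(rng, n_counties, rho))
    tws = np.exp(0.6 * _ar1(rng, n_counties, rho))
    raw_area = np.exp(area_sigma * rng.standard_normal(n_counties))
    area = raw_area / raw_area.sum() * total_area_ha

    counties = pd.DataFrame(
        {
            "county_id": np.arange(n_counties),
            "area_ha": area,
            "climate": climate,
            "aridity": aridity,
            "n_surplus": n_surplus,
            "tws": tws,
        }
    )

    # split each county into cells with Dirichlet(2) shares
    shares = rng.dirichlet(np.full(cells_per_county, 2.0), size=n_counties)
    cell_area = (shares * area[:, None]).ravel()
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_counties * cells_per_county),
            "county_id": np.repeat(np.arange(n_counties), cells_per_county),
            "area_ha": cell_area,
        }
    )
    region = Region(counties=counties, cells=cells)
    region.validate()
    return region


def gen_suitability(
    region: Region,
    cfts: pd.DataFrame,
    fert_rate: np.ndarray | float,
    *,
    climate_shift: float = 0.0,
    seed: int = 0,
    sigma_yield: float = 0.08,
    sigma_water: float = 0.05,
    leach_surplus_gain: float = 0.3,
    soil_n_baseline: float = 0.0,
) -> SuitabilitySurface:
    """Evaluate the suitability surface at given per-county fertilizer rates.

    Yield responds to total nitrogen supply ``f + soil_n_baseline`` (Monod),
    leaching to the applied rate ``f`` only (no fertilizer, no leaching).
    Setting ``sigma_yield = sigma_water = 0`` gives the deterministic surface;
    for fixed seed the multiplicative noise draw is independent of the rates,
    so the surface stays monotone in fertilizer realization-by-realization.
    """
    n = region.n_counties
    J = len(cfts)
    f = np.broadcast_to(np.asarray(fert_rate, dtype=float), (n,)).copy()
    if (f < 0).any():
        raise ValueError("fertilizer rates must be nonnegative")
    if soil_n_baseline < 0:
        raise ValueError("soil_n_baseline must be nonnegative")
    rng = np.random.default_rng(seed)
    eps_y = np.clip(sigma_yield * rng.standard_normal((n, J)), -0.9, None)
    eps_w = np.clip(sigma_water * rng.standard_normal((n, J)), -0.9, None)

    clim = region.counties["climate"].to_numpy()[:, None] + climate_shift
    opt = cfts["clim_opt"].to_numpy()[None, :]
    width = cfts["clim_width"].to_numpy()[None, :]
    suit_clim = np.exp(-((clim - opt) ** 2) / (2.0 * width**2))

    supply = (f + soil_n_baseline)[:, None]
    halfsat = cfts["f_half_kg_ha"].to_numpy()[None, :]
    y = cfts["y_max_t_ha"].to_numpy()[None, :] * suit_clim * supply / (supply + halfsat)
    y = np.clip(y * (1.0 + eps_y), 0.0, None)

    l1 = cfts["leach_l1"].to_numpy()[None, :]
    l2 = cfts["leach_l2_kg_ha"].to_numpy()[None, :]
    fa = f[:, None]
    ns = region.counties["n_surplus"].to_numpy()
    ns_mod = 1.0 + leach_surplus_gain * (ns / ns.mean() - 1.0) if ns.mean() > 0 else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        leach = np.where(fa > 0, l1 * fa * fa / (fa + l2), 0.0)
    leach = np.clip(leach * np.asarray(ns_mod).reshape(-1, 1), 0.0, None)

    arid = region.counties["aridity"].to_numpy()[:, None]
    w = cfts["water_coef_mm"].to_numpy()[None, :] * arid
    w = np.clip(w * (1.0 + eps_w), 0.0, None)

    surf = SuitabilitySurface(
        yield_t_ha=y, leach_kg_ha=leach, irrigation_mm=w, fert_rate=f
    )
    surf.validate()
    return surf


def gen_baseline_allocation(
    region: Region,
    cfts: pd.DataFrame,
    seed: int,
    *,
    bias: float = 3.0,
    n_favored: int = 3,
    reference_rate: float = BASELINE_FERT_RATE,
) -> Allocation:
    """Draw a historical-style baseline allocation.

    Per county, CFT area fractions come from a Dirichlet whose concentration is
    raised by ``bias`` on the county's ``n_favored`` best-yielding CFTs
    (deterministic yields at the reference fertilization rate), emulating
    cropping patterns that historically track local suitability. ``bias = 0``
    reduces to a symmetric Dirichlet(1) (mean fraction 1/J per CFT).
    """
    rng = np.random.default_rng(seed)
    det = gen_suitability(
        region, cfts, reference_rate, sigma_yield=0.0, sigma_water=0.0
    )
    n, J = det.yield_t_ha.shape
    alpha = np.ones((n, J))
    if bias != 0.0:
        order = np.argsort(-det.yield_t_ha, axis=1)[:, :n_favored]
        np.put_along_axis(alpha, order, 1.0 + bias, axis=1)
    fracs = np.empty((n, J))
    for i in range(n):
        fracs[i] = rng.dirichlet(alpha[i])
    areas = fracs * region.areas[:, None]
    alloc = Allocation(areas_ha=areas)
    alloc.check_simplex(region.areas)
    return alloc


@dataclass
class GrowthParams:
    """Socio-economic trajectory parameters (annual rates)."""

    gdp0: float = 12000.0  # constant-currency units per capita at start year
    gdp_growth: float = 0.035  # mean annual exponential growth
    gdp_noise: float = 0.01  # s.d. of annual-rate perturbation per 5-yr step
    pop0: float = 1.41e9  # persons at start year
    pop_capacity: float = 1.45e9  # logistic carrying capacity
    pop_rate: float = 0.02  # logistic intrinsic rate per year


def gen_socioeconomic(
    start_year: int,
    end_year: int,
    seed: int,
    growth: GrowthParams | None = None,
) -> SocioEconomicTrajectory:
    """Generate GDP/population on a 5-year grid: noisy-exponential GDP, logistic population."""
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")
    if start_year % 5 or end_year % 5:
        raise ValueError("years must lie on the 5-year grid")
    g = growth or GrowthParams()
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, end_year + 1, 5)
    steps = len(years)

    gdp = np.empty(steps)
    gdp[0] = g.gdp0
    rates = g.gdp_growth + g.gdp_noise * rng.standard_normal(steps - 1)
    for k in range(1, steps):
        gdp[k] = gdp[k - 1] * np.exp(5.0 * rates[k - 1])

    t = years - start_year
    if g.pop_capacity <= g.pop0:
        pop = np.full(steps, g.pop0)
    else:
        a = (g.pop_capacity - g.pop0) / g.pop0
        pop = g.pop_capacity / (1.0 + a * np.exp(-g.pop_rate * t))
    return SocioEconomicTrajectory(years=years, gdp_per_capita=gdp, population=pop)
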