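"""Crop functional type (CFT) parameter table.

Eleven CFTs represent seven staple crop groups (rice, maize, wheat, soybean,
peanut, potato, rapeseed); crops split into multiple CFTs where sowing season
matters agronomically (early/late/single rice, spring/summer maize,
winter/spring wheat). Demand accounting pools rice, maize and wheat into a
single "cereals" category, giving five self-sufficiency categories in total.

Parameters per CFT:

``calories_kcal_t``
    caloric content of harvested yield, kcal per tonne fresh weight.
``y_max_t_ha``
    potential yield at climatic optimum under nitrogen saturation, t/ha.
``f_half_kg_ha``
    half-saturation nitrogen supply of the Monod yield response, kg N/ha.
``clim_opt`` / ``clim_width``
    optimum and Gaussian tolerance width on the normalized [0, 1] climate
    coordinate (0 ≈ warm/humid south, 1 ≈ cool/dry north).
``leach_l1`` / ``leach_l2_kg_ha``
    convex leaching law n(f) = l1·f²/(f + l2): near-quadratic at low applied
    rates, asymptotically linear with slope l1.
``water_coef_mm``
    irrigation depth demanded per unit aridity index, mm.
"""

from __future__ import annotations

import pandas as pd

CROP_GROUPS = ["rice", "maize", "wheat", "soybean", "peanut", "potato", "rapeseed"]
DEMAND_CATEGORIES = ["cereals", "soybean", "peanut", "potato", "rapeseed"]

#: crop group -> self-sufficiency demand category (cereals pools rice/maize/wheat)
GROUP_TO_CATEGORY = {
    "rice": "cereals",
    "maize": "cereals",
    "wheat": "cereals",
    "soybean": "soybean",
    "peanut": "peanut",
    "potato": "potato",
    "rapeseed": "rapeseed",
}

_DEFAULT_ROWS = [
    # name, group, kcal/t, Ymax, f_half, clim_opt, clim_width, l1, l2, wcoef
    ("rice_early", "rice", 2.80e6, 9.5, 120.0, 0.25, 0.22, 0.28, 90.0, 1100.0),
    ("rice_late", "rice", 2.80e6, 10.0, 130.0, 0.30, 0.22, 0.30, 95.0, 1150.0),
    ("rice_single", "rice", 2.80e6, 11.0, 140.0, 0.45, 0.25, 0.26, 100.0, 1000.0),
    ("maize_spring", "maize", 3.58e6, 13.0, 160.0, 0.65, 0.25, 0.20, 120.0, 550.0),
    ("maize_summer", "maize", 3.58e6, 12.0, 150.0, 0.50, 0.25, 0.22, 110.0, 500.0),
    ("wheat_winter", "wheat", 3.34e6, 9.0, 140.0, 0.55, 0.28, 0.18, 110.0, 420.0),
    ("wheat_spring", "wheat", 3.34e6, 7.5, 120.0, 0.80, 0.24, 0.16, 100.0, 380.0),
    ("soybean", "soybean", 3.60e6, 4.5, 85.0, 0.60, 0.30, 0.12, 80.0, 450.0),
    ("peanut", "peanut", 4.14e6, 5.5, 95.0, 0.40, 0.28, 0.14, 85.0, 400.0),
    ("potato", "potato", 0.70e6, 35.0, 180.0, 0.70, 0.26, 0.24, 130.0, 350.0),
    ("rapeseed", "rapeseed", 4.90e6, 3.8, 150.0, 0.35, 0.30, 0.15, 105.0, 300.0),
]


def build_default_cfts() -> pd.DataFrame:
    """Return the default 11-CFT parameter table (one row per CFT, id 0..10)."""
    df = pd.DataFrame(
        _DEFAULT_ROWS,
        columns=[
            "name",
            "crop_group",
            "calories_kcal_t",
            "y_max_t_ha",
            "f_half_kg_ha",
            "clim_opt",
            "clim_width",
            "leach_l1",
            "leach_l2_kg_ha",
            "water_coef_mm",
        ],
    )
    df.insert(0, "cft_id", range(len(df)))
    df["demand_category"] = df["crop_group"].map(GROUP_TO_CATEGORY)
    validate_cfts(df)
    return df


def validate_cfts(cfts: pd.DataFrame) -> None:
    """Check structural invariants of a CFT table; raise ValueError on breach."""
    if len(cfts) != cfts["cft_id"].nunique():
        raise ValueError("duplicate cft_id")
    unknown = set(cfts["crop_group"]) - set(CROP_GROUPS)
    if unknown:
        raise ValueError(f"unknown crop groups: {unknown}")
    if (cfts["calories_kcal_t"] <= 0).any():
        raise ValueError("caloric contents must be positive")
    bad = cfts["demand_category"] != cfts["crop_group"].map(GROUP_TO_CATEGORY)
    if bad.any():
        raise ValueError("demand_category inconsistent with crop group mapping")
    if (cfts[["leach_l1", "leach_l2_kg_ha"]] < 0).any().any():
        raise ValueError("leach coefficients must be nonnegative")
    if (cfts["clim_width"] <= 0).any():
        raise ValueError("climate tolerance widths must be positive")
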