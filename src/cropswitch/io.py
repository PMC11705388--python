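"""Flat-file formats and aggregation utilities.

Everything is plain CSV (UTF-8, '.' decimal) with a single ``# key=value``
comment header line carrying the generating seed where applicable; YAML for
configuration; JSON for summaries. County and CFT indexing is 0-based
throughout.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cropswitch.synthetic import Allocation, Region, SuitabilitySurface


def _write_csv(df: pd.DataFrame, path: Path, header: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            items = " ".join(f"{k}={v}" for k, v in header.items())
            fh.write(f"# {items}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_region(region: Region, counties_path, cells_path, seed: int | None = None):
    hdr = {"seed": seed} if seed is not None else None
    _write_csv(region.counties, Path(counties_path), hdr)
    _write_csv(region.cells, Path(cells_path), hdr)


def read_region(counties_path, cells_path) -> Region:
    region = Region(counties=_read_csv(counties_path), cells=_read_csv(cells_path))
    region.validate()
    return region


def write_suitability(
    suit: SuitabilitySurface, path, seed: int | None = None
) -> None:
    """One row per county × CFT: county_id, cft_id, yield, leach, irrigation, rate."""
    n, J = suit.yield_t_ha.shape
    df = pd.DataFrame(
        {
            "county_id": np.repeat(np.arange(n), J),
            "cft_id": np.tile(np.arange(J), n),
            "yield_t_ha": suit.yield_t_ha.ravel(),
            "leach_kg_ha": suit.leach_kg_ha.ravel(),
            "irrigation_mm": suit.irrigation_mm.ravel(),
            "fert_rate_kg_ha": np.repeat(suit.fert_rate, J),
        }
    )
    _write_csv(df, Path(path), {"seed": seed} if seed is not None else None)


def read_suitability(path) -> SuitabilitySurface:
    df = _read_csv(path)
    n = df["county_id"].nunique()
    J = df["cft_id"].nunique()
    df = df.sort_values(["county_id", "cft_id"])
    return SuitabilitySurface(
        yield_t_ha=df["yield_t_ha"].to_numpy().reshape(n, J),
        leach_kg_ha=df["leach_kg_ha"].to_numpy().reshape(n, J),
        irrigation_mm=df["irrigation_mm"].to_numpy().reshape(n, J),
        fert_rate=df["fert_rate_kg_ha"].to_numpy().reshape(n, J)[:, 0],
    )


def write_allocation(alloc: Allocation, path, seed: int | None = None) -> None:
    n, J = alloc.areas_ha.shape
    df = pd.DataFrame(
        {
            "county_id": np.repeat(np.arange(n), J),
            "cft_id": np.tile(np.arange(J), n),
            "area_ha": alloc.areas_ha.ravel(),
        }
    )
    _write_csv(df, Path(path), {"seed": seed} if seed is not None else None)


def read_allocation(path) -> Allocation:
    df = _read_csv(path).sort_values(["county_id", "cft_id"])
    n = df["county_id"].nunique()
    J = df["cft_id"].nunique()
    return Allocation(areas_ha=df["area_ha"].to_numpy().reshape(n, J))


def load_yaml(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def config_hash(config: dict) -> str:
    """Stable content hash of a configuration mapping."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def zonal_aggregate(
    cell_values: np.ndarray,
    membership: np.ndarray,
    cell_areas: np.ndarray,
    counties: np.ndarray | None = None,
) -> pd.Series:
    """Area-weighted mean of a per-cell field within each county.

    ``membership`` maps each cell to its county id; ``counties``, when given,
    is the full set of expected county ids — a listed county with no cells is
    an error rather than a silent NaN.
    """
    v = np.asarray(cell_values, dtype=float)
    m = np.asarray(membership)
    a = np.asarray(cell_areas, dtype=float)
    if not (len(v) == len(m) == len(a)):
        raise ValueError("cell arrays must have equal length")
    if (a <= 0).any():
        raise ValueError("cell areas must be positive")
    df = pd.DataFrame({"county": m, "wv": v * a, "w": a})
    g = df.groupby("county").sum()
    means = g["wv"] / g["w"]
    if counties is not None:
        missing = set(np.asarray(counties).tolist()) - set(means.index.tolist())
        if missing:
            raise ValueError(f"counties with zero cells: {sorted(missing)}")
        means = means.reindex(np.asarray(counties))
    means.name = "mean"
    return means
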