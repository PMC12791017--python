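"""Reading and writing boundary-condition grids and result maps.

Grids travel either as long-format CSV (one row per cell) or as
NetCDF; the external-deposit schema is not fixed, so CSV/NetCDF column
names can be remapped via a config-supplied mapping.  NetCDF output
uses the netCDF3-classic backend.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import xarray as xr

from .grid import SITE_COLUMNS, GlobalResult

__all__ = ["load_grid", "save_grid", "save_result_maps", "load_site_table"]

_REQUIRED = [c for c in SITE_COLUMNS if c != "mask"]


def load_grid(path, column_map: dict | None = None) -> pd.DataFrame:
    """Load a boundary-condition grid from CSV or NetCDF.

    ``column_map`` maps file column/variable names to the canonical
    names (lon, lat, area, water_depth, ... mask).
    """
    path = Path(path)
    if path.suffix in {".nc", ".cdf", ".nc4"}:
        ds = xr.open_dataset(path, engine="scipy")
        df = ds.to_dataframe().reset_index()
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"grid file missing columns: {missing}")
    if "mask" not in df.columns:
        df["mask"] = "active"
    if "cell_id" not in df.columns:
        df["cell_id"] = range(len(df))
    return df


def save_grid(grid: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix in {".nc", ".cdf", ".nc4"}:
        ds = xr.Dataset.from_dataframe(grid.set_index("cell_id"))
        # netCDF3 cannot store arbitrary objects; strings are fine
        ds.to_netcdf(path, engine="scipy")
    else:
        grid.to_csv(path, index=False)


def save_result_maps(result: GlobalResult, grid: pd.DataFrame, path) -> None:
    """Per-cell burial maps (z_max, burial rate, total pyrite, Δpyrite)."""
    cells = result.cells.merge(grid[["cell_id", "lon", "lat"]], on="cell_id")
    out = cells[
        ["cell_id", "lon", "lat", "z_max", "j_p", "n_p", "d34s_pyrite", "delta_pyrite"]
    ].rename(
        columns={
            "j_p": "pyrite_burial_rate",
            "n_p": "total_mol_pyrite",
        }
    )
    path = Path(path)
    if path.suffix in {".nc", ".cdf", ".nc4"}:
        xr.Dataset.from_dataframe(out.set_index("cell_id")).to_netcdf(
            path, engine="scipy"
        )
    else:
        out.to_csv(path, index=False)


def load_site_table(path) -> pd.DataFrame:
    """Measured-profile table: (site_id, depth_cm, variable, value[, sd])."""
    df = pd.read_csv(path)
    required = {"site_id", "depth_cm", "variable", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    return df
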