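"""Persistence: NetCDF for raster stacks, CSV for tables, YAML for truth.

Raster layers travel as one NetCDF dataset (classic format via the scipy
backend — one variable per layer with CF-style dimension names, booleans
as int8). Tables use CSV with headers; the generator's truth record uses
YAML; allocation maps get a coded state variable plus a JSON sidecar with
areas and the compensation share.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .scenarios import AllocationMap
from .types import CoarseCropTable, GridStack, TruthRecord

__all__ = [
    "grid_to_dataset",
    "dataset_to_grid",
    "save_grid",
    "load_grid",
    "save_crop_table",
    "load_crop_table",
    "save_truth",
    "load_truth",
    "save_allocation",
]

_BOOL_LAYERS = ("biodiv_priority", "water_scarce", "irrigated")
_FLOAT_LAYERS = (
    "slope_deg", "elevation_m", "ndvi_gs", "regrowth_rate_tC",
    "mai_conif_tC", "mai_nonconif_tC", "agbc_tC", "richness_nat",
    "richness_crop", "whc_mm",
)


def grid_to_dataset(grid: GridStack) -> xr.Dataset:
    dims = ("y", "x")
    data = {
        "land_cover": (dims, grid.land_cover.astype(np.int8)),
        "subregion_id": (dims, grid.subregion_id.astype(np.int32)),
        "degradation_count": (dims, grid.degradation_count.astype(np.int8)),
    }
    for name in _FLOAT_LAYERS:
        data[name] = (dims, getattr(grid, name).astype(np.float64))
    for name in _BOOL_LAYERS:
        data[name] = (dims, getattr(grid, name).astype(np.int8))
    crops = sorted(grid.fert_n_rate)
    data["fert_n_rate"] = (
        ("crop",) + dims,
        np.stack([grid.fert_n_rate[c] for c in crops]),
    )
    data["precip_mm"] = (("month",) + dims, grid.precip_mm)
    data["pet_mm"] = (("month",) + dims, grid.pet_mm)
    subs = sorted(grid.treecover_noncrop)
    data["treecover_noncrop"] = (
        ("subregion",),
        np.array([grid.treecover_noncrop[s] for s in subs]),
    )
    ds = xr.Dataset(
        data,
        coords={
            "crop": np.array(crops, dtype="S32"),
            "month": np.arange(1, 13, dtype=np.int32),
            "subregion": np.array(subs, dtype=np.int32),
        },
        attrs={
            "pixel_area_ha": grid.pixel_area_ha,
            "coarse_factor": grid.coarse_factor,
        },
    )
    return ds


def dataset_to_grid(ds: xr.Dataset) -> GridStack:
    crops = [
        c.decode() if isinstance(c, bytes) else str(c)
        for c in ds["crop"].values
    ]
    fert = {
        c: ds["fert_n_rate"].values[i].astype(float)
        for i, c in enumerate(crops)
    }
    treecover = {
        int(s): float(v)
        for s, v in zip(ds["subregion"].values,
                        ds["treecover_noncrop"].values)
    }
    kwargs = dict(
        land_cover=ds["land_cover"].values.astype(np.int8),
        subregion_id=ds["subregion_id"].values.astype(np.int32),
        degradation_count=ds["degradation_count"].values.astype(np.int8),
        fert_n_rate=fert,
        precip_mm=ds["precip_mm"].values.astype(float),
        pet_mm=ds["pet_mm"].values.astype(float),
        treecover_noncrop=treecover,
        pixel_area_ha=float(ds.attrs["pixel_area_ha"]),
        coarse_factor=int(ds.attrs["coarse_factor"]),
    )
    for name in _FLOAT_LAYERS:
        kwargs[name] = ds[name].values.astype(float)
    for name in _BOOL_LAYERS:
        kwargs[name] = ds[name].values.astype(bool)
    return GridStack(**kwargs)


def save_grid(grid: GridStack, path: str | Path) -> None:
    grid_to_dataset(grid).to_netcdf(path, engine="scipy")


def load_grid(path: str | Path) -> GridStack:
    with xr.open_dataset(path, engine="scipy") as ds:
        return dataset_to_grid(ds.load())


def save_crop_table(table: CoarseCropTable, out_dir: str | Path) -> None:
    out = Path(out_dir)
    table.df.to_csv(out / "crop_table.csv", index=False)
    table.meta.to_csv(out / "crop_metadata.csv")


def load_crop_table(out_dir: str | Path) -> CoarseCropTable:
    out = Path(out_dir)
    df = pd.read_csv(out / "crop_table.csv")
    meta = pd.read_csv(out / "crop_metadata.csv", index_col="crop_id")
    meta["switchable"] = meta["switchable"].astype(bool)
    table = CoarseCropTable(df=df, meta=meta)
    table.validate()
    return table


def _plain(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {_plain(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_truth(truth: TruthRecord, path: str | Path) -> None:
    data = _plain(asdict(truth))
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_truth(path: str | Path) -> TruthRecord:
    return TruthRecord(**yaml.safe_load(Path(path).read_text()))


def save_pixel_crops(pix, path: str | Path) -> None:
    """Persist per-pixel per-crop calories/production/area as NetCDF."""
    dims = ("crop", "y", "x")
    ds = xr.Dataset(
        {
            "calories_kcal": (dims, pix.calories),
            "production_t": (dims, pix.production_t),
            "area_ha": (dims, pix.area_ha),
            "omega": (("y", "x"), pix.omega_layer),
            "cell_id": (("y", "x"), pix.cell_id.astype(np.int32)),
        },
        coords={"crop": np.array(pix.crops, dtype="S32")},
    )
    ds.to_netcdf(path, engine="scipy")


def load_pixel_crops(path: str | Path, meta: pd.DataFrame):
    from .crops import PixelCrops

    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    crops = [
        c.decode() if isinstance(c, bytes) else str(c)
        for c in ds["crop"].values
    ]
    return PixelCrops(
        crops=crops,
        calories=ds["calories_kcal"].values.astype(float),
        production_t=ds["production_t"].values.astype(float),
        area_ha=ds["area_ha"].values.astype(float),
        meta=meta,
        omega_layer=ds["omega"].values.astype(float),
        cell_id=ds["cell_id"].values.astype(np.int64),
    )


def save_allocation(
    alloc: AllocationMap, out_dir: str | Path, name: str
) -> None:
    out = Path(out_dir)
    ds = xr.Dataset(
        {
            "state": (("y", "x"), alloc.state.astype(np.int8)),
            "switched_crop_idx": (
                ("y", "x"), alloc.switched_crop_idx.astype(np.int32)
            ),
            "switched_area_ha": (("y", "x"), alloc.switched_area_ha),
        },
        attrs={"crops": ",".join(alloc.crops)},
    )
    ds.to_netcdf(out / f"allocation_{name}.nc", engine="scipy")
    sidecar = {
        "scenario": name,
        "compensation_share": alloc.compensation_share,
        "deficit_kcal": alloc.deficit_kcal,
        "gain_selected_kcal": alloc.gain_selected_kcal,
        "areas_ha": alloc.areas_ha,
    }
    (out / f"allocation_{name}.json").write_text(
        json.dumps(sidecar, indent=2)
    )
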