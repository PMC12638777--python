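"""Shared fixtures: generated landscapes and a hand-built grid factory."""

from __future__ import annotations

import numpy as np
import pytest

from nexusland.config import ScenarioConfig
from nexusland.pipeline import prepare
from nexusland.synthetic import generate_landscape, load_crop_metadata
from nexusland.types import GridStack, LandCover, LandscapeParams

#: desk-scale landscape used by the deeper suites: 120x120 pixels, 100
#: coarse cells so the mosaic-yield unmixing is identifiable
STANDARD_PARAMS = dict(
    grid_shape=(120, 120), coarse_factor=12, seed=1
)


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape(LandscapeParams(**STANDARD_PARAMS))


@pytest.fixture(scope="session")
def prepared(landscape):
    grid, table, _ = landscape
    cfg = ScenarioConfig()
    sub, omega, pix = prepare(grid, table, cfg)
    return cfg, sub, omega, pix


@pytest.fixture(scope="session")
def outputs(landscape):
    """All eight scenarios run on the standard landscape."""
    from nexusland.pipeline import run_all_scenarios

    grid, table, _ = landscape
    return grid, run_all_scenarios(grid, table, ScenarioConfig())


@pytest.fixture(scope="session")
def crop_meta():
    return load_crop_metadata()


def make_grid(
    land_cover: np.ndarray,
    *,
    slope: float | np.ndarray = 2.0,
    elevation: float | np.ndarray = 300.0,
    ndvi: float | np.ndarray = 4.0,
    subregion: int | np.ndarray = 0,
    biodiv: bool | np.ndarray = False,
    water: bool | np.ndarray = False,
    irrigated: bool | np.ndarray = False,
    degradation: int | np.ndarray = 0,
    regrowth: float | np.ndarray = 1.5,
    mai_conif: float | np.ndarray = 1.8,
    mai_nonconif: float | np.ndarray = 1.6,
    agbc: float | np.ndarray = 15.0,
    richness_nat: float | np.ndarray = 100.0,
    richness_crop: float | np.ndarray = 60.0,
    precip: float | np.ndarray = 100.0,
    pet: float | np.ndarray = 70.0,
    whc: float | np.ndarray = 150.0,
    treecover: float = 0.5,
    fert_rate: float | None = None,
    pixel_area_ha: float = 9.0,
    coarse_factor: int | None = None,
) -> GridStack:
    """Small hand-specified grid with benign defaults for every layer."""
    land_cover = np.asarray(land_cover, dtype=np.int8)
    shape = land_cover.shape

    def full(v, dtype=float):
        return np.broadcast_to(np.asarray(v, dtype=dtype), shape).copy()

    def full12(v):
        return np.broadcast_to(
            np.asarray(v, dtype=float), (12,) + shape
        ).copy()

    meta = load_crop_metadata()
    fert = {
        crop: full(
            fert_rate if fert_rate is not None
            else meta.loc[crop, "fert_n_kg_ha"]
        )
        for crop in meta.index
    }
    sub_arr = full(subregion, np.int32)
    grid = GridStack(
        land_cover=land_cover,
        slope_deg=full(slope),
        elevation_m=full(elevation),
        ndvi_gs=full(ndvi),
        subregion_id=sub_arr,
        biodiv_priority=full(biodiv, bool),
        water_scarce=full(water, bool),
        irrigated=full(irrigated, bool),
        degradation_count=full(degradation, np.int8),
        regrowth_rate_tC=full(regrowth),
        mai_conif_tC=full(mai_conif),
        mai_nonconif_tC=full(mai_nonconif),
        agbc_tC=full(agbc),
        richness_nat=full(richness_nat),
        richness_crop=full(richness_crop),
        fert_n_rate=fert,
        precip_mm=full12(precip),
        pet_mm=full12(pet),
        whc_mm=full(whc),
        treecover_noncrop={
            int(s): treecover for s in np.unique(sub_arr)
        },
        pixel_area_ha=pixel_area_ha,
        coarse_factor=coarse_factor
        if coarse_factor is not None
        else shape[0],
    )
    return grid


@pytest.fixture
def grid_factory():
    return make_grid


# land-cover shorthand for hand-built maps
P, M, N, O = (
    int(LandCover.PURE_CROP),
    int(LandCover.MOSAIC_CROP),
    int(LandCover.NATURAL),
    int(LandCover.OTHER),
)
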