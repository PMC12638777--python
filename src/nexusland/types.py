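"""Core data containers shared across the pipeline.

All raster layers are plain 2-D numpy arrays co-registered on one fine grid
(row-major, 0-based ``(row, col)`` indexing). A coarse grid of
``coarse_factor x coarse_factor`` pixel blocks carries the per-crop
production table, emulating the resolution gap between a ~300 m land-cover
product and a 5 arc-min crop-statistics grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd


class LandCover(IntEnum):
    """Fine-grid land-cover classes.

    ``MOSAIC_CROP`` pixels are assumed to be 50% cropland / 50% non-crop
    vegetation; ``PURE_CROP`` pixels are fully cultivated.
    """

    PURE_CROP = 0
    MOSAIC_CROP = 1
    NATURAL = 2
    OTHER = 3


class AllocState(IntEnum):
    """Per-pixel scenario assignment."""

    UNCHANGED = 0
    RETAIN_WOODY = 1
    REGROW = 2
    AFFOREST = 3
    INTENSIFY = 4
    EXTENSIFY = 5


#: cropland fraction of a pixel by land-cover class
MOSAIC_CROP_FRACTION = 0.5


@dataclass
class LandscapeParams:
    """Configuration of the synthetic landscape generator.

    The defaults emulate a European-style agricultural raster: ~9 ha pixels
    (≈300 m), a 30-pixel coarse cell (≈5 arc-min), cropland covering ~46% of
    the land of which roughly one fifth is mosaic, and a mosaic yield effect
    ``true_omega`` of +9.5% applied to the cropland fraction of mosaic
    pixels.
    """

    grid_shape: tuple[int, int] = (120, 120)
    coarse_factor: int = 30
    pixel_area_ha: float = 9.0
    n_subregions: int = 8
    correlation_length_px: float = 8.0
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "pure_crop": 0.34,
            "mosaic_crop": 0.12,
            "natural": 0.44,
            "other": 0.10,
        }
    )
    true_omega: float = 0.095
    constraint_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "biodiv_priority": 0.30,
            "water_scarce": 0.10,
            "irrigated": 0.08,
        }
    )
    #: fraction of each cell's harvested area under protected crops
    protected_share: float = 0.15
    #: split of the protected share between vegetables / pulses / woody
    protected_split: dict[str, float] = field(
        default_factory=lambda: {
            "vegetables": 0.06,
            "pulses": 0.03,
            "olives_fruit": 0.06,
        }
    )
    #: multiplicative pixel-level lognormal yield noise (coefficient of
    #: variation); 0 disables
    yield_noise_cv: float = 0.05
    #: amplitude of the smooth spatial yield/NDVI productivity field
    yield_spatial_cv: float = 0.10
    #: spread (lognormal sigma) of per-subregion per-crop suitability;
    #: current sown shares are drawn independently of suitability, so the
    #: locally best switchable crop out-yields the present mix — the yield
    #: headroom that crop switching exploits
    crop_suitability_sigma: float = 0.7
    #: per-degree yield decline on terrain steeper than 4 degrees
    slope_yield_penalty: float = 0.04
    #: fraction of mosaic pixels with a missing biomass-carbon value
    agbc_gap_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        if rows % self.coarse_factor or cols % self.coarse_factor:
            raise ValueError(
                f"coarse_factor {self.coarse_factor} does not divide "
                f"grid shape {self.grid_shape}"
            )
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions sum to {total}, expected 1")
        for name, p in self.constraint_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {name}={p} outside [0, 1]")
        if self.pixel_area_ha <= 0:
            raise ValueError("pixel_area_ha must be positive")
        if self.correlation_length_px <= 0:
            raise ValueError("correlation_length_px must be positive")


@dataclass
class GridStack:
    """Co-registered 2-D layers on one fine grid.

    Units: ``slope_deg`` degrees, ``elevation_m`` metres, ``ndvi_gs``
    unitless growing-season cumulative NDVI, carbon rates t C ha-1 yr-1,
    ``agbc_tC`` t C ha-1 (pixel-mean aboveground non-crop biomass; NaN where
    unobserved), richness species per pixel, ``fert_n_rate`` kg N ha-1 yr-1
    per crop, climate mm per month, ``whc_mm`` mm.
    """

    land_cover: np.ndarray
    slope_deg: np.ndarray
    elevation_m: np.ndarray
    ndvi_gs: np.ndarray
    subregion_id: np.ndarray
    biodiv_priority: np.ndarray
    water_scarce: np.ndarray
    irrigated: np.ndarray
    degradation_count: np.ndarray
    regrowth_rate_tC: np.ndarray
    mai_conif_tC: np.ndarray
    mai_nonconif_tC: np.ndarray
    agbc_tC: np.ndarray
    richness_nat: np.ndarray
    richness_crop: np.ndarray
    fert_n_rate: dict[str, np.ndarray]
    precip_mm: np.ndarray  # (12, rows, cols)
    pet_mm: np.ndarray  # (12, rows, cols)
    whc_mm: np.ndarray
    treecover_noncrop: dict[int, float]
    pixel_area_ha: float = 9.0
    coarse_factor: int = 30

    # -- derived helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.land_cover.shape

    @property
    def cropland(self) -> np.ndarray:
        """Boolean mask of pure or mosaic cropland pixels."""
        return (self.land_cover == LandCover.PURE_CROP) | (
            self.land_cover == LandCover.MOSAIC_CROP
        )

    @property
    def crop_fraction(self) -> np.ndarray:
        """Cropland fraction per pixel (1 pure, 0.5 mosaic, 0 otherwise)."""
        frac = np.zeros(self.shape)
        frac[self.land_cover == LandCover.PURE_CROP] = 1.0
        frac[self.land_cover == LandCover.MOSAIC_CROP] = MOSAIC_CROP_FRACTION
        return frac

    def coarse_cell_id(self) -> np.ndarray:
        """Integer coarse-cell index per pixel (row-major over blocks)."""
        rows, cols = self.shape
        f = self.coarse_factor
        r = np.arange(rows) // f
        c = np.arange(cols) // f
        ncols = cols // f
        return (r[:, None] * ncols + c[None, :]).astype(np.int64)

    def n_coarse_cells(self) -> int:
        rows, cols = self.shape
        return (rows // self.coarse_factor) * (cols // self.coarse_factor)

    def validate(self) -> None:
        shp = self.shape
        for name in (
            "slope_deg",
            "elevation_m",
            "ndvi_gs",
            "subregion_id",
            "biodiv_priority",
            "water_scarce",
            "irrigated",
            "degradation_count",
            "regrowth_rate_tC",
            "mai_conif_tC",
            "mai_nonconif_tC",
            "agbc_tC",
            "richness_nat",
            "richness_crop",
            "whc_mm",
        ):
            arr = getattr(self, name)
            if arr.shape != shp:
                raise ValueError(f"layer {name} shape {arr.shape} != {shp}")
        for name in ("precip_mm", "pet_mm"):
            arr = getattr(self, name)
            if arr.shape != (12,) + shp:
                raise ValueError(f"{name} must be a 12-month stack over {shp}")
        for crop, arr in self.fert_n_rate.items():
            if arr.shape != shp:
                raise ValueError(f"fert_n_rate[{crop}] shape mismatch")
        if np.any(self.richness_crop > self.richness_nat + 1e-9):
            raise ValueError("richness_crop must not exceed richness_nat")
        if np.any((self.degradation_count < 0) | (self.degradation_count > 12)):
            raise ValueError("degradation_count outside [0, 12]")
        if not np.all(np.isfinite(self.ndvi_gs[self.cropland])):
            raise ValueError("ndvi_gs not finite on cropland pixels")


@dataclass
class CoarseCropTable:
    """Per-(coarse cell, crop) production and harvested area.

    ``df`` columns: ``coarse_cell_id, crop_id, production_t,
    harvested_area_ha`` (harvest-weight tonnes, physical hectares).
    ``meta`` is indexed by ``crop_id`` with columns ``group`` (cereal, oil,
    root, sugar, vegetable, pulse, woody), ``switchable`` (the 11 switchable
    annual crops), ``dry_fraction``, ``kcal_per_kg_dry``, ``loss_fraction``
    and ``fert_n_kg_ha`` (baseline synthetic-fertilizer rate).
    """

    df: pd.DataFrame
    meta: pd.DataFrame

    def validate(self) -> None:
        missing = set(self.df["crop_id"]) - set(self.meta.index)
        if missing:
            raise ValueError(f"crops without metadata: {sorted(missing)}")
        if (self.df["production_t"] < 0).any():
            raise ValueError("negative production")
        if (self.df["harvested_area_ha"] < 0).any():
            raise ValueError("negative harvested area")
        switchable = set(self.meta.index[self.meta["switchable"]])
        if switchable != set(SWITCHABLE_CROPS):
            raise ValueError(
                f"switchable crops must be exactly {SWITCHABLE_CROPS}, "
                f"got {sorted(switchable)}"
            )


#: the 11 annual crops eligible for crop switching
SWITCHABLE_CROPS = (
    "barley",
    "groundnut",
    "maize",
    "millet",
    "potato",
    "rapeseed",
    "rice",
    "sorghum",
    "soybean",
    "sunflower",
    "wheat",
)

#: crop groups whose cultivation is never converted by any scenario
PROTECTED_GROUPS = ("vegetable", "pulse", "woody")

#: groups with mass-based production entering the calorie total directly
MASS_CAL_GROUPS = ("cereal", "oil", "sugar", "root")


@dataclass
class TruthRecord:
    """Ground truth stored by the generator for parameter-recovery tests."""

    true_omega: dict[int, float]
    realized_class_fractions: dict[str, float]
    planted_suboptimal_fraction: float
    dominant_crop: dict[int, str]
    crop_shares: dict[int, dict[str, float]]
    seed: int
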