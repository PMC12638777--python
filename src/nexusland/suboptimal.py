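"""Suboptimal-cropland classification.

Cropland pixels are flagged as suboptimal by three independent criteria,
combined as a union:

* **slope** — terrain steeper than 8 degrees (strict inequality; ties are
  not suboptimal),
* **fragmentation** — an isolated patch, by default a single cropland pixel
  (~10 ha) with no 8-connected cropland neighbour of either density class,
* **low productivity** — growing-season cumulative NDVI below a subregional
  z-score threshold, with thresholds in [-2, -0.5] assigned by the
  subregion's cropland-abundance rank (lower abundance -> threshold closer
  to 0, flagging relatively more land where farming conditions are poor).

Area accounting counts pure pixels at full pixel area and mosaic pixels at
50%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

from .types import GridStack, LandCover, MOSAIC_CROP_FRACTION

logger = logging.getLogger(__name__)

__all__ = [
    "SuboptimalMap",
    "ZAssignment",
    "map_slope_suboptimal",
    "map_fragmented",
    "cropland_abundance",
    "assign_subregion_zscores",
    "map_low_productive",
    "combine_suboptimal",
    "overlap_stats",
]

_MOORE = np.ones((3, 3), dtype=int)


@dataclass
class ZAssignment:
    """Per-subregion low-productivity z thresholds."""

    thresholds: dict[int, float]
    z_min: float = -2.0
    z_max: float = -0.5
    center: float = -1.25
    sigma: float = 0.375


@dataclass
class SuboptimalMap:
    mask: np.ndarray
    cause_slope: np.ndarray
    cause_fragment: np.ndarray
    cause_lowprod: np.ndarray
    area_ha: float

    def validate(self, grid: GridStack) -> None:
        union = self.cause_slope | self.cause_fragment | self.cause_lowprod
        if not np.array_equal(union, self.mask):
            raise ValueError("mask is not the union of its cause layers")
        if np.any(self.mask & ~grid.cropland):
            raise ValueError("suboptimal mask extends outside cropland")


def map_slope_suboptimal(
    grid: GridStack, threshold_deg: float = 8.0
) -> np.ndarray:
    """Cropland steeper than ``threshold_deg`` (strict)."""
    if threshold_deg <= 0:
        raise ValueError("slope threshold must be positive")
    return grid.cropland & (grid.slope_deg > threshold_deg)


def map_fragmented(
    grid: GridStack,
    max_patch_px: int = 1,
    same_class_only: bool = False,
) -> np.ndarray:
    """Isolated cropland patches.

    With ``max_patch_px=1`` (default, ~10 ha) a cropland pixel is fragmented
    iff none of its 8 Moore neighbours is cropland; either density class
    counts as a neighbour unless ``same_class_only``. Larger values switch
    to an 8-connected component rule (``max_patch_px=2`` approximates the
    20 ha patch alternative). Border pixels use available neighbours only.
    """
    if max_patch_px < 1:
        raise ValueError("max_patch_px must be >= 1")
    out = np.zeros(grid.shape, dtype=bool)
    classes = (
        [np.array([LandCover.PURE_CROP]), np.array([LandCover.MOSAIC_CROP])]
        if same_class_only
        else [np.array([LandCover.PURE_CROP, LandCover.MOSAIC_CROP])]
    )
    for cls in classes:
        member = np.isin(grid.land_cover, cls)
        if max_patch_px == 1:
            nbr = ndimage.convolve(
                member.astype(int), _MOORE, mode="constant", cval=0
            ) - member.astype(int)
            out |= member & (nbr == 0)
        else:
            labels, n = ndimage.label(member, structure=_MOORE)
            if n:
                sizes = np.bincount(labels.ravel())
                small = np.flatnonzero(sizes[1:] <= max_patch_px) + 1
                out |= np.isin(labels, small)
    return out


def cropland_abundance(grid: GridStack) -> pd.Series:
    """Cropland-area share of each subregion (mosaic counted at 50%)."""
    frac = grid.crop_fraction.ravel()
    sub = grid.subregion_id.ravel()
    tot = np.bincount(sub)
    crop = np.bincount(sub, weights=frac)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(tot > 0, crop / np.maximum(tot, 1), 0.0)
    return pd.Series(share, index=np.arange(len(tot)), name="cropland_share")


def assign_subregion_zscores(
    abundance: pd.Series,
    z_min: float = -2.0,
    z_max: float = -0.5,
    center: float = -1.25,
    sigma: float = 0.375,
) -> ZAssignment:
    """Map subregions to z thresholds by cropland-abundance rank.

    Subregions are ranked by cropland abundance; rank ``r`` (1 = lowest
    abundance) of ``S`` subregions receives the ``1 - (r - 0.5)/S`` quantile
    of a Normal(center, sigma) truncated to ``[z_min, z_max]``, so the
    least crop-abundant subregion gets the threshold nearest ``z_max``
    (i.e. closest to 0, flagging the largest share of its cropland).
    """
    if len(abundance) == 0:
        raise ValueError("empty abundance table")
    if not z_min < center < z_max:
        raise ValueError("require z_min < center < z_max")
    a, b = (z_min - center) / sigma, (z_max - center) / sigma
    s = len(abundance)
    ranks = abundance.rank(method="first")  # 1 = lowest abundance
    thresholds = {}
    for sid, r in ranks.items():
        p = 1.0 - (r - 0.5) / s
        thresholds[int(sid)] = float(
            truncnorm.ppf(p, a, b, loc=center, scale=sigma)
        )
    return ZAssignment(
        thresholds=thresholds, z_min=z_min, z_max=z_max, center=center,
        sigma=sigma,
    )


def map_low_productive(grid: GridStack, z_assign: ZAssignment) -> np.ndarray:
    """Cropland with subregionally standardised NDVI below the threshold.

    NDVI is standardised over each subregion's cropland pixels; a zero-SD
    subregion carries no ranking information and flags nothing, as does a
    subregion with fewer than two cropland pixels (warning logged).
    """
    out = np.zeros(grid.shape, dtype=bool)
    cropland = grid.cropland
    for sid, z_thr in z_assign.thresholds.items():
        sel = cropland & (grid.subregion_id == sid)
        n = int(sel.sum())
        if n < 2:
            if n:
                logger.warning(
                    "subregion %s has %d cropland pixel(s); skipped", sid, n
                )
            continue
        vals = grid.ndvi_gs[sel]
        sd = vals.std()
        if sd == 0:
            continue
        z = (grid.ndvi_gs[sel] - vals.mean()) / sd
        flag = np.zeros(grid.shape, dtype=bool)
        flag[sel] = z < z_thr
        out |= flag
    return out


def suboptimal_area_ha(
    mask: np.ndarray, grid: GridStack
) -> float:
    """Area of a cropland mask, mosaic pixels counted at 50%."""
    A = grid.pixel_area_ha
    pure = mask & (grid.land_cover == LandCover.PURE_CROP)
    mosaic = mask & (grid.land_cover == LandCover.MOSAIC_CROP)
    return float(pure.sum() * A + MOSAIC_CROP_FRACTION * mosaic.sum() * A)


def combine_suboptimal(
    slope: np.ndarray,
    fragment: np.ndarray,
    lowprod: np.ndarray,
    grid: GridStack,
) -> SuboptimalMap:
    """Union of the three cause masks with 50%-mosaic area accounting."""
    if not slope.shape == fragment.shape == lowprod.shape == grid.shape:
        raise ValueError("cause masks are not co-registered with the grid")
    mask = slope | fragment | lowprod
    sub = SuboptimalMap(
        mask=mask,
        cause_slope=slope,
        cause_fragment=fragment,
        cause_lowprod=lowprod,
        area_ha=suboptimal_area_ha(mask, grid),
    )
    sub.validate(grid)
    return sub


def identify_suboptimal(
    grid: GridStack,
    slope_threshold_deg: float = 8.0,
    z_min: float = -2.0,
    z_max: float = -0.5,
    z_center: float = -1.25,
    z_sigma: float = 0.375,
    max_patch_px: int = 1,
    same_class_only: bool = False,
) -> SuboptimalMap:
    """Full classification chain with default thresholds."""
    slope = map_slope_suboptimal(grid, slope_threshold_deg)
    frag = map_fragmented(grid, max_patch_px, same_class_only)
    z = assign_subregion_zscores(
        cropland_abundance(grid), z_min, z_max, z_center, z_sigma
    )
    lowprod = map_low_productive(grid, z)
    return combine_suboptimal(slope, frag, lowprod, grid)


def overlap_stats(sub: SuboptimalMap, grid: GridStack) -> pd.Series:
    """Area-weighted overlap of suboptimal cropland with pressure masks.

    Returns fractions of the suboptimal area affected by >=1, exactly 1,
    >=2 (degradation risk) and >=4 degradation processes, and the fractions
    within biodiversity-priority and water-scarcity areas.
    """
    w = grid.crop_fraction * sub.mask * grid.pixel_area_ha
    total = w.sum()
    if total == 0:
        frac = {k: 0.0 for k in (
            "deg_ge1", "deg_eq1", "deg_ge2", "deg_ge4", "biodiv", "water",
        )}
        return pd.Series(frac)
    d = grid.degradation_count
    return pd.Series(
        {
            "deg_ge1": float(w[d >= 1].sum() / total),
            "deg_eq1": float(w[d == 1].sum() / total),
            "deg_ge2": float(w[d >= 2].sum() / total),
            "deg_ge4": float(w[d >= 4].sum() / total),
            "biodiv": float(w[grid.biodiv_priority].sum() / total),
            "water": float(w[grid.water_scarce].sum() / total),
        }
    )
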