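"""Scenario engine: revegetation, constrained greedy conversion, switching.

A scenario combines
* a revegetation option for suboptimal cropland (N: natural regrowth
  everywhere; NA: regrowth inside biodiversity-priority or water-scarce
  areas, afforestation elsewhere), with woody-perennial cropland retained,
* a cropland use mode on the remaining cropland (I: intensify mosaic pixels
  into pure cropland; E: extensify pure pixels into mosaic), and
* a crop switching strategy (HC: highest calorie yield among the 11
  switchable crops; HS: largest current harvested area).

Conversion candidates are ranked lexicographically — extensification first
by an 8-tier constraint priority (biodiversity / water / degradation
combinations), then both modes by neighbouring pure-cropland density
(NPCD, 13x13 window), then net calorie gain, then row-major index — and
selected greedily until the revegetation calorie deficit is compensated.
The marginal pixel is converted in full, so the compensation share can
slightly exceed 1; it falls below 1 when candidates are exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import ScenarioConfig
from .crops import (
    OmegaEstimate,
    PixelCrops,
    revegetation_calorie_deficit,
)
from .suboptimal import SuboptimalMap
from .types import AllocState, GridStack, LandCover

__all__ = [
    "AllocationMap",
    "plan_revegetation",
    "compute_npcd",
    "switch_crop",
    "eligibility_mask",
    "pixel_net_gain",
    "rank_candidates",
    "allocate_until_compensated",
    "run_scenario",
]


@dataclass
class AllocationMap:
    """Per-pixel scenario assignment plus compensation bookkeeping."""

    state: np.ndarray  # int8 AllocState codes
    switched_crop_idx: np.ndarray  # index into crops, -1 where none
    crops: list[str]
    switched_area_ha: np.ndarray
    compensation_share: float
    deficit_kcal: float
    gain_selected_kcal: float
    areas_ha: dict[str, float] = field(default_factory=dict)

    def mask(self, state: AllocState) -> np.ndarray:
        return self.state == state

    def validate(self, grid: GridStack, sub: SuboptimalMap) -> None:
        reveg = (
            self.mask(AllocState.REGROW)
            | self.mask(AllocState.AFFOREST)
            | self.mask(AllocState.RETAIN_WOODY)
        )
        if np.any(reveg & ~sub.mask):
            raise ValueError("revegetation states outside suboptimal mask")
        if np.any(
            self.mask(AllocState.INTENSIFY)
            & (grid.land_cover != LandCover.MOSAIC_CROP)
        ):
            raise ValueError("INTENSIFY outside mosaic cropland")
        if np.any(
            self.mask(AllocState.EXTENSIFY)
            & (grid.land_cover != LandCover.PURE_CROP)
        ):
            raise ValueError("EXTENSIFY outside pure cropland")


def plan_revegetation(
    sub: SuboptimalMap,
    grid: GridStack,
    option: str,
    woody_share: np.ndarray | None = None,
) -> np.ndarray:
    """Assign revegetation states on the suboptimal mask.

    ``woody_share`` is the per-pixel share of crop area under woody
    perennials. Woody perennials (olives, fruit trees) preferentially
    occupy the steep, terraced cropland, so each coarse cell's woody
    pixel-equivalent (woody share summed over its cropland pixels) is
    retained on the steepest suboptimal pixels first, capped at the cell's
    suboptimal count. Option N sends the rest to natural regrowth; option
    NA keeps regrowth inside biodiversity-priority or water-scarce areas
    and afforests elsewhere.
    """
    if option not in ("N", "NA"):
        raise ValueError("revegetation option must be 'N' or 'NA'")
    state = np.full(grid.shape, AllocState.UNCHANGED, dtype=np.int8)
    subopt = sub.mask & grid.cropland
    if woody_share is not None:
        cell_id = grid.coarse_cell_id().ravel()
        flat_sub = subopt.ravel()
        ncells = grid.n_coarse_cells()
        woody_w = np.bincount(
            cell_id,
            weights=woody_share.ravel() * grid.cropland.ravel(),
            minlength=ncells,
        )
        n_retain = np.round(woody_w).astype(int)
        retain = np.zeros(flat_sub.size, dtype=bool)
        # steepest suboptimal pixels first, row-major on ties
        order = np.flatnonzero(flat_sub)
        order = order[np.lexsort((order, -grid.slope_deg.ravel()[order]))]
        cells_of = cell_id[order]
        for cid in np.unique(cells_of):
            k = n_retain[cid]
            if k > 0:
                pick = order[cells_of == cid][:k]
                retain[pick] = True
        retain = retain.reshape(grid.shape)
        state[retain] = AllocState.RETAIN_WOODY
        subopt = subopt & ~retain
    if option == "N":
        state[subopt] = AllocState.REGROW
    else:
        protected_zone = grid.biodiv_priority | grid.water_scarce
        state[subopt & protected_zone] = AllocState.REGROW
        state[subopt & ~protected_zone] = AllocState.AFFOREST
    return state


def compute_npcd(grid: GridStack, window: int = 13) -> np.ndarray:
    """Count of pure-cropland pixels in a centred window, excluding the
    centre; windows are truncated at the grid border."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    pure = (grid.land_cover == LandCover.PURE_CROP).astype(int)
    kernel = np.ones((window, window), dtype=int)
    total = ndimage.convolve(pure, kernel, mode="constant", cval=0)
    return total - pure


def switch_crop(
    calorie_yield: dict[str, float],
    harvested_area: dict[str, float],
    strategy: str,
) -> str:
    """Pick the switched crop of a cell.

    HC: argmax consumer-calorie yield per hectare; HS: argmax current
    harvested area. Ties break alphabetically on crop id.
    """
    if strategy not in ("HC", "HS"):
        raise ValueError("strategy must be 'HC' or 'HS'")
    score = calorie_yield if strategy == "HC" else harvested_area
    candidates = {
        c: v for c, v in score.items() if np.isfinite(v) and v > 0
    }
    if not candidates:
        raise ValueError("no switchable crop with data in this cell")
    return min(candidates, key=lambda c: (-candidates[c], c))


def _cell_switch(
    pix: PixelCrops, grid: GridStack, strategy: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-coarse-cell switched crop index and calorie yield (kcal/ha)."""
    ncells = grid.n_coarse_cells()
    flat_cell = pix.cell_id.ravel()
    switchable = pix.meta.loc[pix.crops, "switchable"].to_numpy()
    crop_idx = np.full(ncells, -1, dtype=np.int32)
    crop_cy = np.full(ncells, np.nan)
    cy = {}
    ar = {}
    for k, crop in enumerate(pix.crops):
        if not switchable[k]:
            continue
        cal = np.bincount(
            flat_cell, weights=pix.calories[k].ravel(), minlength=ncells
        )
        area = np.bincount(
            flat_cell, weights=pix.area_ha[k].ravel(), minlength=ncells
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            cy[crop] = np.where(area > 0, cal / np.maximum(area, 1e-300), np.nan)
        ar[crop] = area
    for cid in range(ncells):
        cy_c = {c: cy[c][cid] for c in cy}
        ar_c = {c: ar[c][cid] for c in ar}
        try:
            chosen = switch_crop(cy_c, ar_c, strategy)
        except ValueError:
            continue
        crop_idx[cid] = pix.crops.index(chosen)
        crop_cy[cid] = cy_c[chosen]
    return crop_idx, crop_cy


def eligibility_mask(
    mode: str,
    grid: GridStack,
    cfg: ScenarioConfig,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Pixels eligible for conversion.

    Intensification is excluded from biodiversity-priority, water-scarce
    and degradation-risk areas and from elevations at or above the
    threshold; extensification has no exclusions. Pixels in ``exclude``
    (the suboptimal mask) are never candidates.
    """
    if mode == "I":
        out = (
            (grid.land_cover == LandCover.MOSAIC_CROP)
            & ~grid.biodiv_priority
            & ~grid.water_scarce
            & (grid.degradation_count < cfg.degradation_risk_min)
            & (grid.elevation_m < cfg.elevation_max_m)
        )
    elif mode == "E":
        out = grid.land_cover == LandCover.PURE_CROP
    else:
        raise ValueError("mode must be 'I' or 'E'")
    if exclude is not None:
        out = out & ~exclude
    return out


def pixel_net_gain(
    pix: PixelCrops,
    grid: GridStack,
    mode: str,
    switched_cy: np.ndarray,
    harvest_rate: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Net calorie gain of converting each pixel, and the switched area.

    Intensification cultivates the whole pixel with the switched crop
    (protected crop area retained at its current absolute extent);
    extensification halves the cultivated area, applies the mosaic yield
    effect ``1 + omega`` to the switched crop, and likewise retains
    protected area. Pixels whose cell has no switchable candidate lose
    their unprotected calories (gain = -current), so they are never
    selected.
    """
    A = grid.pixel_area_ha
    cy_px = switched_cy[pix.cell_id]  # NaN where no candidate
    prot_area = pix.protected_area_ha
    nonprot_cal = pix.unprotected_calories
    if mode == "I":
        switched_area = np.clip(A - prot_area, 0.0, None)
        new_cal = switched_area * cy_px * harvest_rate
    elif mode == "E":
        switched_area = np.clip(0.5 * A - prot_area, 0.0, None)
        new_cal = (
            switched_area * (1.0 + pix.omega_layer) * cy_px * harvest_rate
        )
    else:
        raise ValueError("mode must be 'I' or 'E'")
    gain = np.where(np.isnan(new_cal), -nonprot_cal, new_cal - nonprot_cal)
    return gain, switched_area


def _extensification_tiers(grid: GridStack, cfg: ScenarioConfig) -> np.ndarray:
    b = grid.biodiv_priority
    w = grid.water_scarce
    d = grid.degradation_count >= cfg.degradation_risk_min
    tier = np.full(grid.shape, 8, dtype=np.int8)
    tier[d] = 7
    tier[w] = 6
    tier[b] = 5
    tier[w & d] = 4
    tier[b & d] = 3
    tier[b & w] = 2
    tier[b & w & d] = 1
    return tier


def rank_candidates(
    mode: str,
    grid: GridStack,
    npcd: np.ndarray,
    gains: np.ndarray,
    eligible: np.ndarray,
    cfg: ScenarioConfig,
) -> np.ndarray:
    """Flat pixel indices in conversion priority order (gain > 0 only).

    I: (NPCD desc, gain desc, row-major index asc).
    E: (constraint tier asc, NPCD desc, gain desc, index asc), tiers
    1..8 = B&W&D, B&W, B&D, W&D, B, W, D, rest.
    """
    cand = eligible & (gains > 0)
    idx = np.flatnonzero(cand.ravel())
    if idx.size == 0:
        return idx
    g = gains.ravel()[idx]
    n = npcd.ravel()[idx]
    if mode == "I":
        order = np.lexsort((idx, -g, -n))
    else:
        t = _extensification_tiers(grid, cfg).ravel()[idx]
        order = np.lexsort((idx, -g, -n, t))
    return idx[order]


def allocate_until_compensated(
    ranked_gains: np.ndarray, deficit: float
) -> tuple[int, float]:
    """Greedy prefix selection.

    Returns ``(n_selected, compensation_share)``: pixels are taken in
    ranked order until cumulative gain first reaches the deficit; the
    marginal pixel converts in full. A zero deficit selects nothing
    (share 1); exhausted candidates report the honest share < 1.
    """
    if deficit < 0:
        raise ValueError("deficit must be >= 0")
    if deficit == 0:
        return 0, 1.0
    if ranked_gains.size == 0:
        return 0, 0.0
    cum = np.cumsum(ranked_gains)
    reached = np.flatnonzero(cum >= deficit)
    if reached.size:
        k = int(reached[0]) + 1
        return k, float(cum[k - 1] / deficit)
    return int(ranked_gains.size), float(cum[-1] / deficit)


def run_scenario(
    cfg: ScenarioConfig,
    grid: GridStack,
    pix: PixelCrops,
    sub: SuboptimalMap,
) -> AllocationMap:
    """Compose revegetation, deficit, ranking, allocation and switching."""
    cfg.validate()
    with np.errstate(invalid="ignore", divide="ignore"):
        crop_area = pix.area_ha.sum(axis=0)
        woody = pix.meta.loc[pix.crops, "group"].eq("woody").to_numpy()
        woody_share = np.where(
            crop_area > 0,
            pix.area_ha[woody].sum(axis=0) / np.maximum(crop_area, 1e-300),
            0.0,
        )
    state = plan_revegetation(sub, grid, cfg.reveg_option, woody_share)
    deficit, _ = revegetation_calorie_deficit(pix, sub, grid)

    npcd = compute_npcd(grid, cfg.npcd_window)
    crop_idx_cell, cy_cell = _cell_switch(pix, grid, cfg.switch_strategy)
    gains, switched_area = pixel_net_gain(
        pix, grid, cfg.use_mode, cy_cell, cfg.harvest_rate
    )
    eligible = eligibility_mask(cfg.use_mode, grid, cfg, exclude=sub.mask)
    ranked = rank_candidates(cfg.use_mode, grid, npcd, gains, eligible, cfg)
    n_sel, share = allocate_until_compensated(gains.ravel()[ranked], deficit)
    selected = ranked[:n_sel]

    flat_state = state.ravel()
    flat_state[selected] = (
        AllocState.INTENSIFY if cfg.use_mode == "I" else AllocState.EXTENSIFY
    )
    state = flat_state.reshape(grid.shape)

    switched_crop = np.full(grid.shape, -1, dtype=np.int32)
    sel_mask = np.zeros(grid.shape, dtype=bool)
    sel_mask.ravel()[selected] = True
    switched_crop[sel_mask] = crop_idx_cell[pix.cell_id[sel_mask]]
    switched_area_out = np.where(sel_mask, switched_area, 0.0)

    A = grid.pixel_area_ha
    areas = {
        s.name.lower(): float((state == s).sum() * A) for s in AllocState
    }
    alloc = AllocationMap(
        state=state,
        switched_crop_idx=switched_crop,
        crops=pix.crops,
        switched_area_ha=switched_area_out,
        compensation_share=share,
        deficit_kcal=deficit,
        gain_selected_kcal=float(gains.ravel()[selected].sum()),
        areas_ha=areas,
    )
    alloc.validate(grid, sub)
    return alloc
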