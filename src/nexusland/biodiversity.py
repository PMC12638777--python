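"""Biodiversity pressure as species-richness loss against natural vegetation.

Every pixel's pressure is the difference between the potential species
richness under natural vegetation and the richness supported by its actual
(or scenario) state. Pure cropland carries the cropland richness layer;
mosaic cropland supports 30% more species than pure cropland (capped at the
natural benchmark by default); artificial plantations reach 71% of natural
richness; natural regrowth restores the full natural richness. Summing the
loss over the landscape under current land cover gives BI_CC, under a
scenario allocation BI_AC; the relative reduction (BI_CC - BI_AC)/BI_CC is
the scenario's biodiversity-pressure relief.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ScenarioConfig
from .scenarios import AllocationMap
from .types import AllocState, GridStack, LandCover

__all__ = [
    "PressureResult",
    "mosaic_factor_from_effect",
    "pixel_richness",
    "baseline_richness",
    "pressure",
]


def mosaic_factor_from_effect(effect: float) -> float:
    """Richness multiplier of mosaic over pure cropland from a meta-analytic
    relative effect (e.g. +0.297 -> factor 1.297)."""
    return 1.0 + effect


@dataclass
class PressureResult:
    bi_cc: float
    bi_ac: float
    reduction: float
    loss_baseline: np.ndarray
    loss_scenario: np.ndarray


def _mosaic_richness(grid: GridStack, cfg: ScenarioConfig) -> np.ndarray:
    rich = cfg.mosaic_richness_factor * grid.richness_crop
    if cfg.cap_mosaic_richness:
        rich = np.minimum(grid.richness_nat, rich)
    return rich


def baseline_richness(grid: GridStack, cfg: ScenarioConfig) -> np.ndarray:
    """Species richness under present-day land cover."""
    rich = grid.richness_nat.copy()
    lc = grid.land_cover
    rich[lc == LandCover.PURE_CROP] = grid.richness_crop[
        lc == LandCover.PURE_CROP
    ]
    mosaic = lc == LandCover.MOSAIC_CROP
    rich[mosaic] = _mosaic_richness(grid, cfg)[mosaic]
    return rich


def pixel_richness(
    state: np.ndarray | AllocState,
    grid: GridStack,
    cfg: ScenarioConfig,
) -> np.ndarray:
    """Species richness under a scenario state layer.

    REGROW restores natural richness; AFFOREST reaches the plantation
    factor of it; INTENSIFY drops to pure-cropland richness; EXTENSIFY
    rises to mosaic richness; RETAIN_WOODY stays at cropland richness
    (woody crops remain cultivated); UNCHANGED keeps the baseline value.
    """
    state = np.asarray(state)
    known = np.isin(state, [s.value for s in AllocState])
    if not known.all():
        raise ValueError(
            f"unknown allocation state(s) {np.unique(state[~known])}"
        )
    rich = baseline_richness(grid, cfg)
    rich = np.where(state == AllocState.REGROW, grid.richness_nat, rich)
    rich = np.where(
        state == AllocState.AFFOREST,
        cfg.plantation_richness_factor * grid.richness_nat,
        rich,
    )
    rich = np.where(
        state == AllocState.INTENSIFY, grid.richness_crop, rich
    )
    rich = np.where(
        state == AllocState.EXTENSIFY, _mosaic_richness(grid, cfg), rich
    )
    rich = np.where(
        state == AllocState.RETAIN_WOODY, grid.richness_crop, rich
    )
    return rich


def pressure(
    alloc: AllocationMap | None,
    grid: GridStack,
    cfg: ScenarioConfig,
) -> PressureResult:
    """Baseline and scenario species-loss sums and the relative reduction.

    With ``alloc=None`` the scenario equals the baseline (reduction 0).
    Raises when the baseline pressure is zero (reduction undefined).
    """
    loss_cc = np.clip(grid.richness_nat - baseline_richness(grid, cfg), 0, None)
    bi_cc = float(loss_cc.sum())
    if alloc is None:
        state = np.full(grid.shape, AllocState.UNCHANGED, dtype=np.int8)
    else:
        state = alloc.state
    loss_ac = np.clip(
        grid.richness_nat - pixel_richness(state, grid, cfg), 0, None
    )
    bi_ac = float(loss_ac.sum())
    if bi_cc == 0:
        raise ValueError("baseline biodiversity pressure is zero; "
                         "reduction undefined")
    return PressureResult(
        bi_cc=bi_cc,
        bi_ac=bi_ac,
        reduction=(bi_cc - bi_ac) / bi_cc,
        loss_baseline=loss_cc,
        loss_scenario=loss_ac,
    )
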