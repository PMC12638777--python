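"""Nexus integration: per-scenario indicators, trade-offs and sweeps.

The summary table joins, for each of the eight scenarios, the post-scenario
pure/mosaic cropland areas, the cultivated-equivalent cropland saved
relative to today (mosaic counted at 50%), the calorie compensation share,
the net carbon flux with uncertainty bounds (component-level ranges paired
lowest-with-highest), and the biodiversity-pressure reduction with the
richness-factor confidence bounds.

The carbon-biodiversity trade-off between the two revegetation options of
an otherwise identical scenario is dB = (N - NA) / NA on either the carbon
or the biodiversity benefit. All percentages are computed from unrounded
internals and rounded only at formatting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biodiversity import PressureResult, pressure
from .config import ScenarioConfig
from .fluxes import FluxLedger
from .scenarios import AllocationMap
from .suboptimal import identify_suboptimal
from .types import AllocState, GridStack, LandCover

__all__ = [
    "ScenarioOutputs",
    "tradeoff_eq4",
    "percent_share",
    "mitigation_share",
    "carbon_price_value",
    "carbon_bounds",
    "summarize",
    "tradeoff_table",
    "sensitivity_sweep",
]

#: relative dataset uncertainty applied to flux components for bounds
FLUX_UNCERTAINTY = 0.15
#: 95% CI of the plantation richness factor
PLANTATION_FACTOR_CI = (0.68, 0.74)
#: 95% CI of the mosaic richness factor
MOSAIC_FACTOR_CI = (1.187, 1.407)


@dataclass
class ScenarioOutputs:
    """Everything computed for one scenario."""

    name: str
    cfg: ScenarioConfig
    alloc: AllocationMap
    ledger: FluxLedger
    bio: PressureResult


def tradeoff_eq4(n_benefit: float, na_benefit: float) -> float:
    """Relative benefit difference (N - NA) / NA between the natural-
    regrowth-only and the combined revegetation variant."""
    if na_benefit == 0:
        raise ValueError("NA benefit is zero; trade-off undefined")
    return (n_benefit - na_benefit) / na_benefit


def percent_share(part: float, whole: float) -> float:
    """100 * part / whole."""
    if whole == 0:
        raise ValueError("whole is zero")
    return 100.0 * part / whole


def mitigation_share(net_mt: float, sector_emissions_mt: float) -> float:
    """Net scenario flux as a percentage of a sector's annual emissions."""
    return percent_share(net_mt, sector_emissions_mt)


def carbon_price_value(net_mt: float, price_usd_per_t: float) -> float:
    """Annual value in billion USD of a net flux priced per t CO2-eq."""
    if net_mt < 0 or price_usd_per_t < 0:
        raise ValueError("inputs must be >= 0")
    return net_mt * price_usd_per_t / 1000.0


def carbon_bounds(
    ledger: FluxLedger, rel: float = FLUX_UNCERTAINTY
) -> tuple[float, float]:
    """Net-flux bounds pairing lowest-bound savings with highest-bound
    emissions and vice versa."""
    low = (1 - rel) * ledger.savings - (1 + rel) * ledger.emissions
    high = (1 + rel) * ledger.savings - (1 - rel) * ledger.emissions
    return low, high


def _bio_bounds(
    out: ScenarioOutputs, grid: GridStack
) -> tuple[float, float]:
    vals = []
    for plant, mosaic in zip(PLANTATION_FACTOR_CI, MOSAIC_FACTOR_CI):
        cfg_b = out.cfg.replace(
            plantation_richness_factor=plant, mosaic_richness_factor=mosaic
        )
        vals.append(pressure(out.alloc, grid, cfg_b).reduction)
    return min(vals), max(vals)


def _cultivated_equivalent_ha(
    grid: GridStack, alloc: AllocationMap | None
) -> float:
    frac = grid.crop_fraction
    if alloc is not None:
        state = alloc.state
        frac = frac.copy()
        frac[state == AllocState.REGROW] = 0.0
        frac[state == AllocState.AFFOREST] = 0.0
        frac[state == AllocState.INTENSIFY] = 1.0
        frac[state == AllocState.EXTENSIFY] = 0.5
    return float(frac.sum() * grid.pixel_area_ha)


def summarize(
    outputs: dict[str, ScenarioOutputs], grid: GridStack
) -> pd.DataFrame:
    """One indicator row per scenario (absent scenarios listed as such)."""
    A = grid.pixel_area_ha
    baseline_equiv = _cultivated_equivalent_ha(grid, None)
    rows = []
    for name, out in outputs.items():
        if out is None:
            rows.append({"scenario": name, "status": "absent"})
            continue
        state = out.alloc.state
        unchanged = state == AllocState.UNCHANGED
        pure_after = (
            (unchanged & (grid.land_cover == LandCover.PURE_CROP))
            | (state == AllocState.INTENSIFY)
        )
        mosaic_after = (
            (unchanged & (grid.land_cover == LandCover.MOSAIC_CROP))
            | (state == AllocState.EXTENSIFY)
        )
        net_low, net_high = carbon_bounds(out.ledger)
        red_low, red_high = _bio_bounds(out, grid)
        rows.append(
            {
                "scenario": name,
                "status": "ok",
                "pure_area_ha": float(pure_after.sum() * A),
                "mosaic_area_ha": float(mosaic_after.sum() * A),
                "saved_cropland_ha": baseline_equiv
                - _cultivated_equivalent_ha(grid, out.alloc),
                "compensation_share": out.alloc.compensation_share,
                "net_carbon_mt": out.ledger.net,
                "net_carbon_low_mt": net_low,
                "net_carbon_high_mt": net_high,
                "bio_reduction": out.bio.reduction,
                "bio_reduction_low": red_low,
                "bio_reduction_high": red_high,
            }
        )
    return pd.DataFrame(rows).set_index("scenario")


def tradeoff_table(outputs: dict[str, ScenarioOutputs]) -> pd.DataFrame:
    """Carbon and biodiversity trade-offs of N vs NA revegetation for each
    (use mode, switching strategy) pair present in ``outputs``."""
    rows = []
    pairs = sorted(
        {name.rsplit("-", 1)[0] for name in outputs if outputs[name]}
    )
    for stem in pairs:
        n_out = outputs.get(f"{stem}-N")
        na_out = outputs.get(f"{stem}-NA")
        if n_out is None or na_out is None:
            continue
        rows.append(
            {
                "pair": stem,
                "delta_b_carbon": tradeoff_eq4(
                    n_out.ledger.net, na_out.ledger.net
                ),
                "delta_b_biodiv": tradeoff_eq4(
                    n_out.bio.reduction, na_out.bio.reduction
                ),
            }
        )
    return pd.DataFrame(rows).set_index("pair")


def sensitivity_sweep(
    grid: GridStack,
    base_cfg: ScenarioConfig,
    overrides: list[dict],
) -> pd.DataFrame:
    """Re-run the suboptimal classification under config overrides.

    Each override is a dict of ``ScenarioConfig`` field replacements (e.g.
    ``{"slope_threshold_deg": 7.0}``); the result rows carry the override
    and the resulting suboptimal area and cause-mask areas.
    """
    if not overrides:
        raise ValueError("override list is empty")
    rows = []
    for ov in overrides:
        cfg = base_cfg.replace(**ov)
        sub = identify_suboptimal(
            grid,
            slope_threshold_deg=cfg.slope_threshold_deg,
            z_min=cfg.z_min,
            z_max=cfg.z_max,
            z_center=cfg.z_center,
            z_sigma=cfg.z_sigma,
            max_patch_px=cfg.frag_max_patch_px,
            same_class_only=cfg.frag_same_class_only,
        )
        w = grid.crop_fraction * grid.pixel_area_ha
        rows.append(
            {
                **ov,
                "suboptimal_area_ha": sub.area_ha,
                "slope_area_ha": float(w[sub.cause_slope].sum()),
                "fragment_area_ha": float(w[sub.cause_fragment].sum()),
                "lowprod_area_ha": float(w[sub.cause_lowprod].sum()),
            }
        )
    return pd.DataFrame(rows)
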