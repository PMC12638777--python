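"""End-to-end drivers tying the stages together."""

from __future__ import annotations

from .biodiversity import pressure
from .config import ScenarioConfig
from .crops import downscale_production, estimate_mosaic_yield_effect
from .fluxes import scenario_fluxes
from .reporting import ScenarioOutputs
from .scenarios import run_scenario
from .suboptimal import identify_suboptimal
from .synthetic import generate_landscape
from .types import CoarseCropTable, GridStack, LandscapeParams

__all__ = ["SCENARIO_NAMES", "run_one", "run_all_scenarios", "prepare"]

SCENARIO_NAMES = tuple(
    f"{m}-{s}-{r}"
    for m in ("I", "E")
    for s in ("HC", "HS")
    for r in ("N", "NA")
)


def prepare(grid: GridStack, table: CoarseCropTable, cfg: ScenarioConfig):
    """Shared pre-scenario stages: suboptimal map, omega, pixel calories."""
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
    omega = estimate_mosaic_yield_effect(table, grid)
    pix = downscale_production(
        table, grid, omega, waste=cfg.waste,
        veg_pulse_share=cfg.veg_pulse_share,
    )
    return sub, omega, pix


def run_one(
    cfg: ScenarioConfig,
    grid: GridStack,
    table: CoarseCropTable,
    sub=None,
    pix=None,
) -> ScenarioOutputs:
    """Run a single scenario end to end."""
    if sub is None or pix is None:
        sub, _, pix = prepare(grid, table, cfg)
    alloc = run_scenario(cfg, grid, pix, sub)
    ledger = scenario_fluxes(alloc, pix, grid, cfg)
    bio = pressure(alloc, grid, cfg)
    return ScenarioOutputs(
        name=cfg.scenario_name, cfg=cfg, alloc=alloc, ledger=ledger, bio=bio
    )


def run_all_scenarios(
    grid: GridStack,
    table: CoarseCropTable,
    base_cfg: ScenarioConfig | None = None,
) -> dict[str, ScenarioOutputs]:
    """All eight scenarios on one landscape, sharing the pre-stages."""
    base_cfg = base_cfg or ScenarioConfig()
    sub, _, pix = prepare(grid, table, base_cfg)
    out: dict[str, ScenarioOutputs] = {}
    for name in SCENARIO_NAMES:
        mode, strategy, reveg = name.split("-")
        cfg = base_cfg.replace(
            use_mode=mode, switch_strategy=strategy, reveg_option=reveg
        )
        out[name] = run_one(cfg, grid, table, sub=sub, pix=pix)
    return out


def simulate(params: LandscapeParams | None = None):
    """Generate a default synthetic landscape."""
    return generate_landscape(params or LandscapeParams())
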