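"""30-year-average annual carbon ledger per scenario.

Savings side: aboveground carbon sequestration from natural regrowth (the
first-30-year mean accumulation rate), afforestation (best of coniferous /
non-coniferous mean annual stem increment, scaled by a 20% branch factor),
tree planting on the non-crop half of extensified pixels, plus avoided soil
N2O from abandoning fertilisation on revegetated suboptimal cropland and on
the pre-switch crops of converted pixels.

Emissions side: immediate oxidation of the non-crop biomass cleared by
intensification (amortised over 30 years), one-time forestry-operation
emissions of plantation establishment (0.30 t CO2/ha on suboptimal
cropland, 0.15 t CO2/ha in mosaics, amortised the same way), and the soil
N2O of the newly planted switched crops.

Direct soil N2O follows an exponential response to the nitrogen rate x:

    Y(x) = I(x) - I(0),
    I(x) = exp[((mu0+s0^2)^2 - mu0^2)/(2 s0^2)]
         * exp[((mu1+s1^2 x)^2 - mu1^2)/(2 s1^2)]

(kg N2O-N ha-1 yr-1). Indirect N2O uses the IPCC volatilisation pathway
always and the leaching pathway only where irrigation is present or rainy
season precipitation minus potential evapotranspiration exceeds the soil
water-holding capacity; rainy months are those wetter than one third of
the wettest month. N2O-N converts to N2O by 44/28 and to CO2-eq by GWP100.

Internal canonical unit is t CO2-eq yr-1 per pixel; ledger totals are Mt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import N2OParams, ScenarioConfig
from .crops import PixelCrops
from .scenarios import AllocationMap
from .types import AllocState, GridStack, LandCover

__all__ = [
    "FluxLedger",
    "seq_revegetation",
    "clearing_emissions",
    "mosaic_planting_sequestration",
    "n2o_direct",
    "n2o_indirect",
    "leaching_mask",
    "n2o_scenario_delta",
    "build_ledger",
    "scenario_fluxes",
]

C_TO_CO2 = 44.0 / 12.0
N2ON_TO_N2O = 44.0 / 28.0
T_PER_MT = 1e6


@dataclass
class FluxLedger:
    """Component carbon flows of one scenario, Mt CO2-eq yr-1."""

    seq_regrowth: float = 0.0
    seq_afforest: float = 0.0
    seq_mosaic_planting: float = 0.0
    avoided_n2o_reveg: float = 0.0
    avoided_n2o_switchoff: float = 0.0
    emis_clearing: float = 0.0
    emis_forestry_ops: float = 0.0
    emis_n2o_newcrops: float = 0.0

    @property
    def savings(self) -> float:
        return (
            self.seq_regrowth
            + self.seq_afforest
            + self.seq_mosaic_planting
            + self.avoided_n2o_reveg
            + self.avoided_n2o_switchoff
        )

    @property
    def emissions(self) -> float:
        return (
            self.emis_clearing
            + self.emis_forestry_ops
            + self.emis_n2o_newcrops
        )

    @property
    def net(self) -> float:
        return self.savings - self.emissions

    def as_dict(self) -> dict[str, float]:
        out = {
            k: getattr(self, k)
            for k in (
                "seq_regrowth", "seq_afforest", "seq_mosaic_planting",
                "avoided_n2o_reveg", "avoided_n2o_switchoff",
                "emis_clearing", "emis_forestry_ops", "emis_n2o_newcrops",
            )
        }
        out.update(savings=self.savings, emissions=self.emissions,
                   net=self.net)
        return out


def seq_revegetation(
    alloc: AllocationMap, grid: GridStack, cfg: ScenarioConfig
) -> dict[str, np.ndarray]:
    """Sequestration (t CO2/yr per pixel) on REGROW and AFFOREST pixels,
    plus the amortised forestry-operation emissions of afforestation."""
    for layer in (grid.regrowth_rate_tC, grid.mai_conif_tC,
                  grid.mai_nonconif_tC):
        if np.any(layer < 0):
            raise ValueError("negative carbon accumulation rate")
    A = grid.pixel_area_ha
    regrow = alloc.mask(AllocState.REGROW)
    afforest = alloc.mask(AllocState.AFFOREST)
    seq_regrow = np.where(regrow, grid.regrowth_rate_tC * C_TO_CO2 * A, 0.0)
    best_mai = np.maximum(grid.mai_conif_tC, grid.mai_nonconif_tC)
    seq_aff = np.where(
        afforest, best_mai * cfg.branch_factor * C_TO_CO2 * A, 0.0
    )
    ops = np.where(
        afforest,
        cfg.forestry_emis_reveg_tco2_ha * A / cfg.amortization_yr,
        0.0,
    )
    return {"seq_regrowth": seq_regrow, "seq_afforest": seq_aff,
            "emis_forestry_ops": ops}


def fill_agbc(
    grid: GridStack, window: int = 13
) -> np.ndarray:
    """AGBC layer with gaps filled by the windowed mosaic-pixel mean.

    Pixels whose value is missing receive the mean AGBC of mosaic cropland
    pixels inside a centred ``window x window`` neighbourhood; raises with
    the offending pixel list if a gap has no observed mosaic neighbour.
    """
    agbc = grid.agbc_tC.copy()
    missing = ~np.isfinite(agbc)
    if not missing.any():
        return agbc
    from scipy import ndimage

    mosaic_obs = (grid.land_cover == LandCover.MOSAIC_CROP) & ~missing
    kernel = np.ones((window, window))
    vals = np.where(mosaic_obs, np.nan_to_num(agbc), 0.0)
    s = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    n = ndimage.convolve(mosaic_obs.astype(float), kernel, mode="constant",
                         cval=0.0)
    fillable = missing & (n > 0)
    agbc[fillable] = s[fillable] / n[fillable]
    unfilled = missing & (n == 0)
    if unfilled.any():
        bad = [tuple(int(v) for v in rc) for rc in np.argwhere(unfilled)]
        raise ValueError(
            f"AGBC gaps without mosaic neighbours at pixels {bad[:20]}"
            + ("..." if len(bad) > 20 else "")
        )
    return agbc


def clearing_emissions(
    alloc: AllocationMap, grid: GridStack, cfg: ScenarioConfig
) -> np.ndarray:
    """Annualised clearing emissions (t CO2/yr) on INTENSIFY pixels."""
    intens = alloc.mask(AllocState.INTENSIFY)
    if not intens.any():
        return np.zeros(grid.shape)
    agbc = fill_agbc(grid, cfg.npcd_window)
    A = grid.pixel_area_ha
    return np.where(
        intens, agbc * C_TO_CO2 * A / cfg.amortization_yr, 0.0
    )


def mosaic_planting_sequestration(
    alloc: AllocationMap, grid: GridStack, cfg: ScenarioConfig
) -> dict[str, np.ndarray]:
    """Tree planting on the non-crop half of EXTENSIFY pixels.

    Non-coniferous species are planted on the subregional tree-cover share
    of the revegetated half; the net pixel flux is floored at zero."""
    ext = alloc.mask(AllocState.EXTENSIFY)
    shape = grid.shape
    if not ext.any():
        return {"seq_mosaic_planting": np.zeros(shape),
                "emis_forestry_ops": np.zeros(shape)}
    tc = np.zeros(shape)
    for sid in np.unique(grid.subregion_id[ext]):
        if int(sid) not in grid.treecover_noncrop:
            raise ValueError(f"missing subregion tree cover for {sid}")
        tc[grid.subregion_id == sid] = grid.treecover_noncrop[int(sid)]
    A = grid.pixel_area_ha
    planted_ha = 0.5 * A * tc
    seq = np.where(
        ext,
        grid.mai_nonconif_tC * cfg.branch_factor * C_TO_CO2 * tc * 0.5 * A,
        0.0,
    )
    ops = np.where(
        ext,
        cfg.forestry_emis_mosaic_tco2_ha * planted_ha / cfg.amortization_yr,
        0.0,
    )
    neg = seq - ops < 0
    seq[neg], ops[neg] = 0.0, 0.0  # floor net planting flux at zero
    return {"seq_mosaic_planting": seq, "emis_forestry_ops": ops}


def n2o_direct(
    x: float | np.ndarray, p: N2OParams
) -> float | np.ndarray:
    """Direct N2O emission rate Y(x) = I(x) - I(0), kg N2O-N ha-1 yr-1."""
    if p.sigma0 <= 0 or p.sigma1 <= 0:
        raise ValueError("sigma0 and sigma1 must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("nitrogen rate must be >= 0")
    s0sq = p.sigma0**2
    s1sq = p.sigma1**2
    base = np.exp(((p.mu0 + s0sq) ** 2 - p.mu0**2) / (2.0 * s0sq))

    def factor1(xx):
        return np.exp(((p.mu1 + s1sq * xx) ** 2 - p.mu1**2) / (2.0 * s1sq))

    out = base * (factor1(x) - factor1(0.0))
    return out if out.ndim else float(out)


def leaching_mask(grid: GridStack) -> np.ndarray:
    """True where the IPCC leaching pathway applies.

    Leaching occurs under irrigation, or when rainy-season precipitation
    minus rainy-season PET exceeds the soil water-holding capacity. Rainy
    months are those with precipitation above one third of the wettest
    month's.
    """
    wettest = grid.precip_mm.max(axis=0)
    rainy = grid.precip_mm > wettest / 3.0
    p_rainy = np.where(rainy, grid.precip_mm, 0.0).sum(axis=0)
    pet_rainy = np.where(rainy, grid.pet_mm, 0.0).sum(axis=0)
    return grid.irrigated | (p_rainy - pet_rainy > grid.whc_mm)


def n2o_indirect(
    x: float | np.ndarray,
    leaching: bool | np.ndarray,
    p: N2OParams,
) -> float | np.ndarray:
    """Indirect N2O, kg N2O-N ha-1 yr-1 (volatilisation + leaching)."""
    x = np.asarray(x, dtype=float)
    out = x * p.frac_volatilized * p.ef_volatilization + np.where(
        leaching, x * p.frac_leached * p.ef_leaching, 0.0
    )
    return out if out.ndim else float(out)


def n2o_scenario_delta(
    alloc: AllocationMap,
    pix: PixelCrops,
    grid: GridStack,
    cfg: ScenarioConfig,
) -> dict[str, float]:
    """Avoided and added soil-N2O flows of a scenario, Mt CO2-eq yr-1.

    Avoided: fertilisation of all crops on revegetated suboptimal pixels
    and of the cleared (unprotected) pre-switch crops on converted pixels.
    Added: fertilisation of the switched crop on its planted area.
    """
    p = cfg.n2o
    leach = leaching_mask(grid)
    to_co2 = N2ON_TO_N2O * cfg.gwp100_n2o / 1e9  # kg N2O-N -> Mt CO2-eq

    rate = {}  # kg N2O-N per crop-ha at each pixel
    for crop in pix.crops:
        x = grid.fert_n_rate[crop]
        rate[crop] = n2o_direct(x, p) + n2o_indirect(x, leach, p)

    reveg = alloc.mask(AllocState.REGROW) | alloc.mask(AllocState.AFFOREST)
    converted = alloc.mask(AllocState.INTENSIFY) | alloc.mask(
        AllocState.EXTENSIFY
    )
    avoided_reveg = 0.0
    avoided_switch = 0.0
    added = 0.0
    for k, crop in enumerate(pix.crops):
        area = pix.area_ha[k]
        avoided_reveg += float((rate[crop] * area)[reveg].sum())
        if not pix.protected[k]:
            avoided_switch += float((rate[crop] * area)[converted].sum())
    for k, crop in enumerate(pix.crops):
        on = converted & (alloc.switched_crop_idx == k)
        if on.any():
            added += float(
                (rate[crop] * alloc.switched_area_ha)[on].sum()
            )
    return {
        "avoided_n2o_reveg": avoided_reveg * to_co2,
        "avoided_n2o_switchoff": avoided_switch * to_co2,
        "emis_n2o_newcrops": added * to_co2,
    }


def build_ledger(components: dict[str, float | np.ndarray]) -> FluxLedger:
    """Aggregate component layers/values (t CO2/yr or Mt for scalars
    already reduced) into a scenario ledger in Mt CO2-eq yr-1."""
    fields = FluxLedger.__dataclass_fields__
    agg: dict[str, float] = {}
    for name, value in components.items():
        if name not in fields:
            raise KeyError(f"unknown ledger component {name!r}")
        if isinstance(value, np.ndarray):
            agg[name] = agg.get(name, 0.0) + float(value.sum()) / T_PER_MT
        else:
            agg[name] = agg.get(name, 0.0) + float(value)
    return FluxLedger(**agg)


def scenario_fluxes(
    alloc: AllocationMap,
    pix: PixelCrops,
    grid: GridStack,
    cfg: ScenarioConfig,
) -> FluxLedger:
    """Full carbon ledger of one scenario."""
    reveg = seq_revegetation(alloc, grid, cfg)
    planting = mosaic_planting_sequestration(alloc, grid, cfg)
    clearing = clearing_emissions(alloc, grid, cfg)
    n2o = n2o_scenario_delta(alloc, pix, grid, cfg)
    return build_ledger(
        {
            "seq_regrowth": reveg["seq_regrowth"],
            "seq_afforest": reveg["seq_afforest"],
            "seq_mosaic_planting": planting["seq_mosaic_planting"],
            "emis_clearing": clearing,
            "emis_forestry_ops": reveg["emis_forestry_ops"]
            + planting["emis_forestry_ops"],
            **n2o,
        }
    )
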