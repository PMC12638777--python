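"""Crop production downscaling and calorie accounting.

Coarse-cell harvest-weight production is converted to consumer-level
calories (dry-matter conversion, food waste, supply-chain loss), then
distributed over the cell's cropland pixels with weight 1 for pure and
``0.5 * (1 + omega)`` for mosaic pixels, where omega is the relative yield
effect of non-crop vegetation on the cropland fraction of mosaic pixels.

The calorie supply of vegetables and pulses is set to 10% of the cell's
cereal + oil + sugar + root calories (a reference-diet share), woody crops
carry no calories (their cultivation is always retained), and omega is
estimated per subregion by unmixing cell mean per-cropland-hectare yields
against the pure/mosaic area composition.

The calorie loss from revegetating suboptimal cropland in a coarse cell is

    loss = total_cal * [0.5 (1+w) N_SM + N_SP] / [0.5 (1+w) N_M + N_P]

with N_M / N_P the mosaic / pure cropland pixel counts of the cell and
N_SM / N_SP the cleared suboptimal subsets; summing downscaled pixel
calories over cleared pixels evaluates the same quantity exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .suboptimal import SuboptimalMap
from .types import (
    CoarseCropTable,
    GridStack,
    LandCover,
    MASS_CAL_GROUPS,
    MOSAIC_CROP_FRACTION,
    PROTECTED_GROUPS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OmegaEstimate",
    "PixelCrops",
    "crop_calories",
    "cell_calories",
    "downscale_production",
    "estimate_mosaic_yield_effect",
    "calorie_loss_eq1",
    "revegetation_calorie_deficit",
]

DEFAULT_WASTE = 0.17


def crop_calories(
    production_t: float | np.ndarray,
    meta_row: pd.Series,
    waste: float = DEFAULT_WASTE,
) -> float | np.ndarray:
    """Consumer-level kcal from harvest-weight tonnes.

    kcal = t * 1000 * dry_fraction * kcal_per_kg_dry * (1 - waste)
           * (1 - loss_fraction)
    """
    for key in ("dry_fraction", "kcal_per_kg_dry", "loss_fraction"):
        if key not in meta_row or pd.isna(meta_row[key]):
            raise KeyError(
                f"incomplete metadata for crop "
                f"{meta_row.name!r}: missing {key}"
            )
    return (
        production_t
        * 1000.0
        * meta_row["dry_fraction"]
        * meta_row["kcal_per_kg_dry"]
        * (1.0 - waste)
        * (1.0 - meta_row["loss_fraction"])
    )


def cell_calories(
    table: CoarseCropTable,
    waste: float = DEFAULT_WASTE,
    veg_pulse_share: float = 0.10,
) -> pd.DataFrame:
    """Per-(cell, crop) consumer-level calories.

    Mass crops (cereal/oil/sugar/root) are converted directly; vegetables
    and pulses are assigned ``veg_pulse_share`` of the cell's mass-crop
    calories (split between them by harvested area); woody crops are zero.
    """
    df = table.df.copy()
    meta = table.meta
    df["group"] = meta.loc[df["crop_id"], "group"].to_numpy()
    kcal = np.zeros(len(df))
    is_mass = df["group"].isin(MASS_CAL_GROUPS).to_numpy()
    for crop, idx in df[is_mass].groupby("crop_id").groups.items():
        kcal[df.index.get_indexer(idx)] = crop_calories(
            df.loc[idx, "production_t"].to_numpy(), meta.loc[crop], waste
        )
    df["kcal"] = kcal
    mass_by_cell = df[is_mass].groupby("coarse_cell_id")["kcal"].sum()

    is_vp = df["group"].isin(("vegetable", "pulse")).to_numpy()
    vp = df[is_vp]
    if len(vp):
        area_by_cell = vp.groupby("coarse_cell_id")["harvested_area_ha"].sum()
        budget = veg_pulse_share * mass_by_cell.reindex(
            vp["coarse_cell_id"]
        ).fillna(0.0).to_numpy()
        denom = area_by_cell.reindex(vp["coarse_cell_id"]).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(denom > 0, vp["harvested_area_ha"] / denom, 0.0)
        df.loc[is_vp, "kcal"] = budget * w
    return df[["coarse_cell_id", "crop_id", "group", "kcal"]]


@dataclass
class OmegaEstimate:
    """Per-subregion mosaic yield effect with a pooled fallback."""

    per_subregion: dict[int, float]
    se: dict[int, float]
    n_cells: dict[int, int]
    pooled: float
    pooled_se: float = float("nan")

    def value(self, subregion: int) -> float:
        """Subregional estimate, falling back to the pooled one; a fully
        unidentifiable effect falls back to 0 (no mosaic yield effect)."""
        w = self.per_subregion.get(subregion, float("nan"))
        if np.isfinite(w):
            return w
        return self.pooled if np.isfinite(self.pooled) else 0.0

    def layer(self, grid: GridStack) -> np.ndarray:
        out = np.full(
            grid.shape, self.pooled if np.isfinite(self.pooled) else 0.0
        )
        for sid in np.unique(grid.subregion_id):
            out[grid.subregion_id == sid] = self.value(int(sid))
        return out


def _omega_layer(omega, grid: GridStack) -> np.ndarray:
    if isinstance(omega, OmegaEstimate):
        return omega.layer(grid)
    return np.full(grid.shape, float(omega))


@dataclass
class PixelCrops:
    """Per-pixel, per-crop calories, production and physical crop area.

    Arrays are stacked ``(n_crops, rows, cols)`` in the order of ``crops``.
    Mosaic pixels already carry the ``0.5 (1 + omega)`` calorie weighting.
    """

    crops: list[str]
    calories: np.ndarray
    production_t: np.ndarray
    area_ha: np.ndarray
    meta: pd.DataFrame
    omega_layer: np.ndarray
    cell_id: np.ndarray
    protected: np.ndarray = field(init=False)  # per-crop boolean

    def __post_init__(self) -> None:
        groups = self.meta.loc[self.crops, "group"]
        self.protected = groups.isin(PROTECTED_GROUPS).to_numpy()

    @property
    def total_calories(self) -> np.ndarray:
        return self.calories.sum(axis=0)

    @property
    def protected_calories(self) -> np.ndarray:
        return self.calories[self.protected].sum(axis=0)

    @property
    def unprotected_calories(self) -> np.ndarray:
        return self.calories[~self.protected].sum(axis=0)

    @property
    def protected_area_ha(self) -> np.ndarray:
        return self.area_ha[self.protected].sum(axis=0)


def downscale_production(
    table: CoarseCropTable,
    grid: GridStack,
    omega: OmegaEstimate | float,
    waste: float = DEFAULT_WASTE,
    veg_pulse_share: float = 0.10,
) -> PixelCrops:
    """Distribute coarse-cell production and calories over cropland pixels.

    Calories and production use the yield weighting (1 pure,
    ``0.5 (1+omega)`` mosaic); physical harvested area uses the area
    weighting (1 pure, 0.5 mosaic). Cells with production but no cropland
    pixels are logged and skipped.
    """
    cell_id = grid.coarse_cell_id()
    ncells = grid.n_coarse_cells()
    frac = grid.crop_fraction.ravel()
    flat_cell = cell_id.ravel()
    w_omega = _omega_layer(omega, grid)
    is_mosaic = (grid.land_cover == LandCover.MOSAIC_CROP).ravel()
    w_yield = frac * np.where(is_mosaic, 1.0 + w_omega.ravel(), 1.0)

    wsum_yield = np.bincount(flat_cell, weights=w_yield, minlength=ncells)
    wsum_area = np.bincount(flat_cell, weights=frac, minlength=ncells)

    cal = cell_calories(table, waste, veg_pulse_share)
    cal = cal.merge(
        table.df[["coarse_cell_id", "crop_id", "production_t",
                  "harvested_area_ha"]],
        on=["coarse_cell_id", "crop_id"],
    )
    crops = sorted(table.meta.index)
    shape = grid.shape
    n = len(crops)
    calories = np.zeros((n,) + shape)
    production = np.zeros((n,) + shape)
    area = np.zeros((n,) + shape)

    for k, crop in enumerate(crops):
        rows = cal[cal["crop_id"] == crop]
        if rows.empty:
            continue
        cell_cal = np.zeros(ncells)
        cell_prod = np.zeros(ncells)
        cell_area = np.zeros(ncells)
        cid = rows["coarse_cell_id"].to_numpy()
        cell_cal[cid] = rows["kcal"].to_numpy()
        cell_prod[cid] = rows["production_t"].to_numpy()
        cell_area[cid] = rows["harvested_area_ha"].to_numpy()
        empty = (cell_cal + cell_prod > 0) & (wsum_yield == 0)
        if empty.any():
            logger.warning(
                "crop %s: %d cell(s) with production but no cropland "
                "pixels skipped", crop, int(empty.sum()),
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            share_y = np.where(
                wsum_yield[flat_cell] > 0,
                w_yield / np.maximum(wsum_yield[flat_cell], 1e-300),
                0.0,
            )
            share_a = np.where(
                wsum_area[flat_cell] > 0,
                frac / np.maximum(wsum_area[flat_cell], 1e-300),
                0.0,
            )
        calories[k] = (cell_cal[flat_cell] * share_y).reshape(shape)
        production[k] = (cell_prod[flat_cell] * share_y).reshape(shape)
        area[k] = (cell_area[flat_cell] * share_a).reshape(shape)

    return PixelCrops(
        crops=crops,
        calories=calories,
        production_t=production,
        area_ha=area,
        meta=table.meta,
        omega_layer=w_omega,
        cell_id=cell_id,
    )


def estimate_mosaic_yield_effect(
    table: CoarseCropTable,
    grid: GridStack,
    n_min: int = 10,
) -> OmegaEstimate:
    """Unmix the mosaic yield effect from coarse-cell composition.

    For each coarse cell the mean per-cropland-hectare production of the
    mass crops is regressed (OLS, intercept suppressed) on the composition
    vector ``(1 - f, f)`` where ``f`` is the mosaic share of the cell's
    physical cropland area; the fitted pure and mosaic-fraction yields give
    ``omega = y_m / y_p - 1``. Subregions with too few cells or no
    composition variation fall back to the continental pooled estimate.
    """
    cell_id = grid.coarse_cell_id()
    ncells = grid.n_coarse_cells()
    flat_cell = cell_id.ravel()
    lc = grid.land_cover.ravel()
    n_pure = np.bincount(
        flat_cell, weights=(lc == LandCover.PURE_CROP), minlength=ncells
    )
    n_mosaic = np.bincount(
        flat_cell, weights=(lc == LandCover.MOSAIC_CROP), minlength=ncells
    )
    crop_area = grid.pixel_area_ha * (
        n_pure + MOSAIC_CROP_FRACTION * n_mosaic
    )

    mass_crops = table.meta.index[
        table.meta["group"].isin(MASS_CAL_GROUPS)
    ]
    mass = table.df[table.df["crop_id"].isin(mass_crops)]
    prod = np.zeros(ncells)
    by_cell = mass.groupby("coarse_cell_id")["production_t"].sum()
    prod[by_cell.index.to_numpy()] = by_cell.to_numpy()

    # majority-cropland subregion per cell; cells whose cropland straddles
    # subregion borders mix different base yields and would bias the
    # composition regression, so only near-pure cells enter the fit
    sub_flat = grid.subregion_id.ravel()
    frac = grid.crop_fraction.ravel()
    nsub = int(sub_flat.max()) + 1
    w2 = np.zeros((ncells, nsub))
    np.add.at(w2, (flat_cell, sub_flat), frac)
    cell_sub = np.argmax(w2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.where(
            w2.sum(axis=1) > 0,
            w2.max(axis=1) / np.maximum(w2.sum(axis=1), 1e-300),
            0.0,
        )

    valid = (crop_area > 0) & (purity > 0.999)
    y = np.where(valid, prod / np.maximum(crop_area, 1e-300), np.nan)
    f = np.where(
        valid,
        MOSAIC_CROP_FRACTION * n_mosaic
        / np.maximum(n_pure + MOSAIC_CROP_FRACTION * n_mosaic, 1e-300),
        np.nan,
    )

    def fit(idx: np.ndarray) -> tuple[float, float]:
        """OLS of y on (1-f, f); returns (omega, se)."""
        fi, yi = f[idx], y[idx]
        if len(fi) < 2 or np.std(fi) < 1e-9:
            return float("nan"), float("nan")
        X = np.column_stack([1.0 - fi, fi])
        coef, res, rank, _ = np.linalg.lstsq(X, yi, rcond=None)
        if rank < 2 or coef[0] <= 0:
            return float("nan"), float("nan")
        yp, ym = coef
        dof = len(fi) - 2
        if dof > 0:
            resid = yi - X @ coef
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(X.T @ X)
            var = (
                cov[1, 1] / yp**2
                + ym**2 * cov[0, 0] / yp**4
                - 2 * ym * cov[0, 1] / yp**3
            )
            se = float(np.sqrt(max(var, 0.0)))
        else:
            se = float("nan")
        return float(ym / yp - 1.0), se

    def pooled_fit(idx: np.ndarray) -> tuple[float, float]:
        """Common omega with subregion-specific base yields.

        Alternates between (a) base yield per subregion given omega and
        (b) the least-squares omega given the base yields; reduces to the
        plain two-parameter OLS when only one subregion is present.
        """
        groups = cell_sub[idx]
        uniq = np.unique(groups)
        if len(uniq) == 1:
            return fit(idx)
        fi, yi = f[idx], y[idx]
        if np.std(fi) < 1e-9:
            return float("nan"), float("nan")
        w = 0.0
        for _ in range(100):
            denom = (1.0 - fi) + (1.0 + w) * fi
            yp = np.zeros(len(fi))
            for g in uniq:
                sel = groups == g
                yp[sel] = np.mean(yi[sel] / denom[sel])
            s = yp * fi
            ss = float(s @ s)
            if ss <= 0:
                return float("nan"), float("nan")
            w_new = float(s @ (yi - yp)) / ss
            if abs(w_new - w) < 1e-12:
                w = w_new
                break
            w = w_new
        resid = yi - yp * ((1.0 - fi) + (1.0 + w) * fi)
        dof = len(fi) - len(uniq) - 1
        s2 = float(resid @ resid) / dof if dof > 0 else np.nan
        return w, float(np.sqrt(s2 / ss)) if dof > 0 else float("nan")

    all_idx = np.flatnonzero(valid)
    pooled, pooled_se = pooled_fit(all_idx)
    if not np.isfinite(pooled):
        logger.warning(
            "no pure/mosaic composition variation: pooled mosaic yield "
            "effect is not identifiable"
        )

    per_sub: dict[int, float] = {}
    se: dict[int, float] = {}
    n_cells: dict[int, int] = {}
    for sid in range(nsub):
        idx = np.flatnonzero(valid & (cell_sub == sid))
        n_cells[sid] = len(idx)
        if len(idx) >= n_min:
            per_sub[sid], se[sid] = fit(idx)
        else:
            per_sub[sid], se[sid] = float("nan"), float("nan")
        if not np.isfinite(per_sub[sid]):
            logger.warning(
                "subregion %d: mosaic yield effect not identifiable "
                "(%d cells); using pooled estimate", sid, len(idx),
            )
    return OmegaEstimate(
        per_subregion=per_sub, se=se, n_cells=n_cells,
        pooled=pooled, pooled_se=pooled_se,
    )


def calorie_loss_eq1(
    counts: tuple[float, float, float, float],
    omega: float,
    total_cal: float,
) -> float:
    """Calorie loss of one coarse cell from clearing its suboptimal pixels.

    ``counts = (N_M, N_P, N_SM, N_SP)``: mosaic/pure cropland pixel counts
    and their cleared suboptimal subsets.
    """
    n_m, n_p, n_sm, n_sp = counts
    if n_m == 0 and n_p == 0:
        raise ValueError("cell has no cropland pixels: loss undefined")
    if not (0 <= n_sm <= n_m and 0 <= n_sp <= n_p):
        raise ValueError("suboptimal counts exceed cropland counts")
    w = MOSAIC_CROP_FRACTION * (1.0 + omega)
    return total_cal * (w * n_sm + n_sp) / (w * n_m + n_p)


def revegetation_calorie_deficit(
    pix: PixelCrops,
    sub: SuboptimalMap,
    grid: GridStack,
) -> tuple[float, pd.Series]:
    """Total calorie loss from clearing suboptimal cropland.

    All annual crops (and the vegetable/pulse supply) on suboptimal
    cropland are cleared; the retained woody-crop area is excluded
    implicitly because woody crops carry no calories in the accounting.
    Also returns the per-crop dry-mass losses (mass crops, tonnes dry
    weight).
    """
    cleared = sub.mask & grid.cropland
    deficit = float(pix.total_calories[cleared].sum())
    mass_sel = pix.meta.loc[pix.crops, "group"].isin(MASS_CAL_GROUPS)
    losses = {}
    for k, crop in enumerate(pix.crops):
        if mass_sel.iloc[k]:
            losses[crop] = float(
                pix.production_t[k][cleared].sum()
                * pix.meta.loc[crop, "dry_fraction"]
            )
    return deficit, pd.Series(losses, name="dry_mass_loss_t")
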