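"""Synthetic raster landscapes with known ground truth.

Every downstream stage of the pipeline (suboptimal-cropland mapping, calorie
accounting, scenario allocation, flux and biodiversity scoring) is exercised
on landscapes built here, so the generator emulates the statistical structure
of the continental data stack it stands in for: spatially autocorrelated
terrain/productivity fields, two cropland density classes (pure, and mosaic
at 50% cropland), contiguous subregions, per-crop production on a coarse
grid, constraint masks with tunable prevalence, and a known mosaic yield
effect omega applied to the cropland fraction of mosaic pixels.

Fields are produced by frequency-domain smoothing of white noise (an
O(N log N) Gaussian random field with controllable correlation length);
class maps by thresholding a smooth field at quantiles; subregions by a
Voronoi partition of random seed points.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .types import (
    CoarseCropTable,
    GridStack,
    LandCover,
    LandscapeParams,
    MOSAIC_CROP_FRACTION,
    SWITCHABLE_CROPS,
    TruthRecord,
)

__all__ = [
    "gaussian_field",
    "voronoi_subregions",
    "generate_landscape",
    "load_crop_metadata",
]

#: Dirichlet concentration for the non-protected crop-share draw, loosely
#: following European sown-area rankings (wheat > maize > barley > ...).
_CROP_ALPHA = {
    "wheat": 6.0,
    "barley": 4.0,
    "maize": 1.5,
    "rapeseed": 3.0,
    "sunflower": 2.0,
    "potato": 1.0,
    "soybean": 1.0,
    "sugarbeet": 0.5,
    "rice": 0.5,
    "sorghum": 0.5,
    "millet": 0.5,
    "groundnut": 0.5,
}


def load_crop_metadata() -> pd.DataFrame:
    """Crop metadata table shipped with the package (indexed by crop_id)."""
    ref = importlib.resources.files("nexusland").joinpath(
        "data/crop_metadata.csv"
    )
    with ref.open("r") as fh:
        meta = pd.read_csv(fh, index_col="crop_id")
    meta["switchable"] = meta["switchable"].astype(bool)
    return meta


def gaussian_field(
    shape: tuple[int, int], correlation_length_px: float, seed: int
) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field.

    White noise is smoothed with a Gaussian kernel of scale
    ``correlation_length_px`` in the frequency domain (circular boundary),
    then re-standardised. Deterministic given ``seed``.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    if correlation_length_px <= 0:
        raise ValueError("correlation_length_px must be > 0")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    ky = np.fft.fftfreq(rows)[:, None]
    kx = np.fft.fftfreq(cols)[None, :]
    # Gaussian transfer of a smoothing kernel with sd L/2: calibrated so
    # sub-pixel L leaves the field near-white (lag-1 autocorrelation
    # ~0.12 at L=0.5) while L of a few pixels is strongly smooth
    kernel = np.exp(
        -0.5 * (np.pi * correlation_length_px) ** 2 * (ky**2 + kx**2)
    )
    smooth = np.fft.ifft2(np.fft.fft2(white) * kernel).real
    sd = smooth.std()
    if sd < 1e-12:  # pathological: kernel wiped all variance
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def voronoi_subregions(
    shape: tuple[int, int], n_subregions: int, seed: int
) -> np.ndarray:
    """Contiguous integer subregion labels from a random Voronoi partition."""
    rows, cols = shape
    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [rng.uniform(0, rows, n_subregions), rng.uniform(0, cols, n_subregions)]
    )
    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = (rr[..., None] - pts[:, 0]) ** 2 + (cc[..., None] - pts[:, 1]) ** 2
    return np.argmin(d2, axis=-1).astype(np.int32)


def _rank_gauss(field: np.ndarray) -> np.ndarray:
    """Quantile-map a field to an exact standard-normal marginal.

    Keeps the spatial pattern but pins the landscape-level distribution,
    so planted tail fractions (steep terrain, degradation counts) do not
    drift with the field realisation.
    """
    from scipy.stats import norm

    flat = field.ravel()
    ranks = np.empty_like(flat)
    ranks[np.argsort(flat, kind="stable")] = np.arange(flat.size)
    return norm.ppf((ranks + 0.5) / flat.size).reshape(field.shape)


def _threshold_mask(field: np.ndarray, prevalence: float) -> np.ndarray:
    """Boolean mask covering the top ``prevalence`` share of a field."""
    if prevalence <= 0:
        return np.zeros(field.shape, dtype=bool)
    if prevalence >= 1:
        return np.ones(field.shape, dtype=bool)
    return field > np.quantile(field, 1.0 - prevalence)


def _omega_by_subregion(params: LandscapeParams) -> dict[int, float]:
    if isinstance(params.true_omega, dict):
        return {int(k): float(v) for k, v in params.true_omega.items()}
    return {s: float(params.true_omega) for s in range(params.n_subregions)}


def generate_landscape(
    params: LandscapeParams,
) -> tuple[GridStack, CoarseCropTable, TruthRecord]:
    """Generate a co-registered landscape, coarse crop table and truth record.

    Coarse-cell production is the exact pixel aggregate of per-pixel yields
    under the mosaic ``0.5 * (1 + omega)`` weighting, so mass consistency
    between the table and any downscaling holds by construction.
    """
    params.validate()
    shape = params.grid_shape
    rows, cols = shape
    A = params.pixel_area_ha
    L = params.correlation_length_px
    rng = np.random.default_rng(params.seed)

    def sub_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    def smooth() -> np.ndarray:
        return gaussian_field(shape, L, sub_seed())

    # --- land cover by quantile thresholds of one smooth field ----------
    u = smooth()
    order = ["pure_crop", "mosaic_crop", "natural", "other"]
    codes = [
        LandCover.PURE_CROP,
        LandCover.MOSAIC_CROP,
        LandCover.NATURAL,
        LandCover.OTHER,
    ]
    cum = np.cumsum([params.class_fractions[k] for k in order])
    edges = np.quantile(u, cum[:-1])
    land_cover = np.full(shape, codes[-1], dtype=np.int8)
    prev = -np.inf
    for code, edge in zip(codes[:-1], edges):
        land_cover[(u > prev) & (u <= edge)] = code
        prev = edge

    subregion_id = voronoi_subregions(shape, params.n_subregions, sub_seed())

    # --- terrain, productivity, constraints ------------------------------
    # degradation pressure and biodiversity priority co-vary with steep
    # terrain (mountainous land is both more erodible and more valuable
    # for conservation), so the steep-slope suboptimal class overlaps
    # substantially with both masks
    z_slope = _rank_gauss(smooth())
    slope_deg = 2.8 * np.exp(0.75 * z_slope)
    elevation_m = np.clip(450.0 + 320.0 * smooth(), 0.0, None)
    g_prod = smooth()  # shared productivity gradient (NDVI and yields)
    ndvi_noise = np.random.default_rng(sub_seed()).standard_normal(shape)
    # NDVI tracks the same productivity gradient as yields, including the
    # slope fall-off, so the low-productivity class overlaps steep terrain
    # rather than forming an independent 10% draw of the cropland
    slope_factor = np.clip(
        1.0 - params.slope_yield_penalty * np.maximum(slope_deg - 4.0, 0.0),
        0.3,
        1.0,
    )
    ndvi_gs = (4.0 + 1.2 * g_prod + 0.15 * ndvi_noise) - 8.0 * (
        1.0 - slope_factor
    )

    prev_cfg = params.constraint_prevalence
    biodiv_priority = _threshold_mask(
        0.5 * z_slope + 0.866 * smooth(), prev_cfg["biodiv_priority"]
    )
    water_scarce = _threshold_mask(smooth(), prev_cfg["water_scarce"])
    irrigated = _threshold_mask(smooth(), prev_cfg.get("irrigated", 0.0))
    degradation_count = np.clip(
        np.floor(
            1.0 + 2.2 * _rank_gauss(0.6 * z_slope + 0.8 * smooth())
        ),
        0,
        12,
    ).astype(np.int8)

    regrowth_rate_tC = np.clip(1.5 + 0.5 * smooth(), 0.2, 4.0)
    mai_conif_tC = np.clip(1.8 + 0.5 * smooth(), 0.2, 4.0)
    mai_nonconif_tC = np.clip(1.6 + 0.5 * smooth(), 0.2, 4.0)
    agbc_tC = np.clip(15.0 + 6.0 * smooth(), 2.0, 60.0)
    gap_rng = np.random.default_rng(sub_seed())
    gaps = (land_cover == LandCover.MOSAIC_CROP) & (
        gap_rng.random(shape) < params.agbc_gap_fraction
    )
    agbc_tC[gaps] = np.nan

    richness_nat = np.clip(55.0 + 15.0 * smooth(), 5.0, None)
    richness_crop = richness_nat * np.clip(0.65 + 0.08 * smooth(), 0.30, 0.92)

    month = np.arange(12)
    g_pr = smooth()
    g_pet = smooth()
    precip_mm = np.clip(
        (55.0 + 30.0 * np.cos(2 * np.pi * month / 12))[:, None, None]
        * (1.0 + 0.25 * g_pr)[None],
        1.0,
        None,
    )
    pet_mm = np.clip(
        (70.0 + 50.0 * np.cos(2 * np.pi * (month - 6) / 12))[:, None, None]
        * (1.0 + 0.20 * g_pet)[None],
        1.0,
        None,
    )
    whc_mm = np.clip(140.0 + 40.0 * smooth(), 50.0, 260.0)

    meta = load_crop_metadata()
    g_fert = smooth()
    fert_mult = np.clip(1.0 + 0.2 * g_fert, 0.3, 2.0)
    fert_n_rate = {
        crop: meta.loc[crop, "fert_n_kg_ha"] * fert_mult for crop in meta.index
    }

    tree_rng = np.random.default_rng(sub_seed())
    treecover_noncrop = {
        s: float(0.25 + 0.4 * tree_rng.random())
        for s in range(params.n_subregions)
    }

    # --- crop structure per subregion ------------------------------------
    omega = _omega_by_subregion(params)
    share_rng = np.random.default_rng(sub_seed())
    suit_rng = np.random.default_rng(sub_seed())
    alpha = np.array([_CROP_ALPHA[c] for c in _CROP_ALPHA])
    nonprot_total = 1.0 - params.protected_share
    crop_shares: dict[int, dict[str, float]] = {}
    for s in range(params.n_subregions):
        draw = share_rng.dirichlet(alpha) * nonprot_total
        shares = dict(zip(_CROP_ALPHA, draw))
        shares.update(params.protected_split)
        crop_shares[s] = shares
    # agro-ecological suitability per crop, constant within a subregion
    # (lognormal spread sigma); sown shares are drawn independently of it,
    # so the locally best crop out-yields the present mix
    sigma = params.crop_suitability_sigma
    suitability: dict[str, np.ndarray] = {}
    for crop in meta.index:
        z_sub = suit_rng.standard_normal(params.n_subregions)
        suitability[crop] = np.exp(sigma * z_sub)[subregion_id]

    # --- per-pixel yields aggregated to the coarse table -----------------
    crop_frac = np.zeros(shape)
    crop_frac[land_cover == LandCover.PURE_CROP] = 1.0
    crop_frac[land_cover == LandCover.MOSAIC_CROP] = MOSAIC_CROP_FRACTION
    is_mosaic = land_cover == LandCover.MOSAIC_CROP

    # yields follow the NDVI productivity gradient and fall off on steep
    # terrain, so suboptimal cropland supplies less than its area share
    yield_mult = np.clip(1.0 + params.yield_spatial_cv * g_prod, 0.2, None)
    yield_mult = yield_mult * slope_factor
    if params.yield_noise_cv > 0:
        cv = params.yield_noise_cv
        noise_rng = np.random.default_rng(sub_seed())
        yield_mult = yield_mult * np.exp(
            cv * noise_rng.standard_normal(shape) - 0.5 * cv**2
        )

    omega_layer = np.zeros(shape)
    for s, w in omega.items():
        omega_layer[subregion_id == s] = w
    yield_weight = yield_mult * np.where(is_mosaic, 1.0 + omega_layer, 1.0)

    ncells = (rows // params.coarse_factor) * (cols // params.coarse_factor)
    f = params.coarse_factor
    cell_id = (
        (np.arange(rows) // f)[:, None] * (cols // f)
        + (np.arange(cols) // f)[None, :]
    ).astype(np.int64)
    flat_cell = cell_id.ravel()
    flat_frac = crop_frac.ravel()
    flat_yw = (yield_weight).ravel()
    flat_sub = subregion_id.ravel()

    records = []
    for crop in meta.index:
        base_y = meta.loc[crop, "base_yield_t_ha"]
        share_px = np.array(
            [crop_shares[s].get(crop, 0.0)
             for s in range(params.n_subregions)]
        )[flat_sub]
        suit_px = suitability[crop].ravel()
        area_px = flat_frac * A * share_px  # physical crop ha per pixel
        prod_px = base_y * suit_px * flat_yw * area_px
        prod_cell = np.bincount(flat_cell, weights=prod_px, minlength=ncells)
        area_cell = np.bincount(flat_cell, weights=area_px, minlength=ncells)
        for cid in range(ncells):
            if area_cell[cid] > 0:
                records.append(
                    (cid, crop, float(prod_cell[cid]), float(area_cell[cid]))
                )
    table = CoarseCropTable(
        df=pd.DataFrame(
            records,
            columns=[
                "coarse_cell_id",
                "crop_id",
                "production_t",
                "harvested_area_ha",
            ],
        ),
        meta=meta,
    )

    grid = GridStack(
        land_cover=land_cover,
        slope_deg=slope_deg,
        elevation_m=elevation_m,
        ndvi_gs=ndvi_gs,
        subregion_id=subregion_id,
        biodiv_priority=biodiv_priority,
        water_scarce=water_scarce,
        irrigated=irrigated,
        degradation_count=degradation_count,
        regrowth_rate_tC=regrowth_rate_tC,
        mai_conif_tC=mai_conif_tC,
        mai_nonconif_tC=mai_nonconif_tC,
        agbc_tC=agbc_tC,
        richness_nat=richness_nat,
        richness_crop=richness_crop,
        fert_n_rate=fert_n_rate,
        precip_mm=precip_mm,
        pet_mm=pet_mm,
        whc_mm=whc_mm,
        treecover_noncrop=treecover_noncrop,
        pixel_area_ha=A,
        coarse_factor=params.coarse_factor,
    )
    grid.validate()
    table.validate()

    n_px = land_cover.size
    realized = {
        "pure_crop": float((land_cover == LandCover.PURE_CROP).sum() / n_px),
        "mosaic_crop": float((land_cover == LandCover.MOSAIC_CROP).sum() / n_px),
        "natural": float((land_cover == LandCover.NATURAL).sum() / n_px),
        "other": float((land_cover == LandCover.OTHER).sum() / n_px),
    }
    crop_w = crop_frac.sum()
    steep_w = crop_frac[slope_deg > 8.0].sum()
    switch_set = set(SWITCHABLE_CROPS)
    dominant = {
        s: max(
            (c for c in crop_shares[s] if c in switch_set),
            key=lambda c: crop_shares[s][c],
        )
        for s in range(params.n_subregions)
    }
    truth = TruthRecord(
        true_omega=omega,
        realized_class_fractions=realized,
        planted_suboptimal_fraction=float(steep_w / crop_w) if crop_w else 0.0,
        dominant_crop=dominant,
        crop_shares=crop_shares,
        seed=params.seed,
    )
    return grid, table, truth
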