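"""Revegetation planning, NPCD, switching, ranking and greedy allocation,
including the brute-force minimal-prefix oracle."""

import numpy as np
import pandas as pd
import pytest

from nexusland.config import ScenarioConfig
from nexusland.crops import PixelCrops, downscale_production
from nexusland.scenarios import (
    allocate_until_compensated,
    compute_npcd,
    eligibility_mask,
    pixel_net_gain,
    plan_revegetation,
    rank_candidates,
    run_scenario,
    switch_crop,
)
from nexusland.suboptimal import SuboptimalMap
from nexusland.types import AllocState, CoarseCropTable, LandCover
from tests.conftest import M, N, P, make_grid


def make_sub(mask, grid):
    mask = np.asarray(mask, dtype=bool)
    return SuboptimalMap(
        mask=mask,
        cause_slope=mask,
        cause_fragment=np.zeros_like(mask),
        cause_lowprod=np.zeros_like(mask),
        area_ha=float(mask.sum() * grid.pixel_area_ha),
    )


def single_crop_pix(grid, crop_meta, cal_per_pixel, crop="wheat",
                    protected_cal=0.0, protected_area=0.0):
    """One-crop PixelCrops with a per-pixel calorie layer (cell = pixel)."""
    crops = sorted(crop_meta.index)
    shape = grid.shape
    n = len(crops)
    calories = np.zeros((n,) + shape)
    production = np.zeros((n,) + shape)
    area = np.zeros((n,) + shape)
    k = crops.index(crop)
    calories[k] = cal_per_pixel
    area[k] = grid.crop_fraction * grid.pixel_area_ha
    if protected_cal or protected_area:
        kp = crops.index("vegetables")
        calories[kp] = protected_cal
        area[kp] = protected_area
    return PixelCrops(
        crops=crops,
        calories=calories,
        production_t=production,
        area_ha=area,
        meta=crop_meta,
        omega_layer=np.zeros(shape),
        cell_id=grid.coarse_cell_id(),
    )


class TestPlanRevegetation:
    def test_option_n_all_regrow(self):
        grid = make_grid(np.full((2, 2), P))
        sub = make_sub(np.ones((2, 2), bool), grid)
        state = plan_revegetation(sub, grid, "N", woody_share=None)
        assert (state == AllocState.REGROW).all()

    def test_option_na_splits_by_masks(self):
        biodiv = np.array([[True, False], [False, False]])
        water = np.array([[False, True], [False, False]])
        grid = make_grid(np.full((2, 2), P), biodiv=biodiv, water=water)
        sub = make_sub(np.ones((2, 2), bool), grid)
        state = plan_revegetation(sub, grid, "NA", woody_share=None)
        assert state[0, 0] == AllocState.REGROW
        assert state[0, 1] == AllocState.REGROW
        assert state[1, 0] == AllocState.AFFOREST
        assert state[1, 1] == AllocState.AFFOREST

    def test_woody_retained_on_steepest(self):
        grid = make_grid(
            np.full((2, 2), P),
            slope=np.array([[12.0, 9.0], [10.0, 2.0]]),
            coarse_factor=2,
        )
        sub = make_sub(np.array([[True, True], [True, False]]), grid)
        # 25% woody share over 4 cropland pixels -> retain 1 pixel,
        # the steepest suboptimal one (slope 12)
        woody = np.full((2, 2), 0.25)
        state = plan_revegetation(sub, grid, "N", woody)
        assert state[0, 0] == AllocState.RETAIN_WOODY
        assert state[0, 1] == AllocState.REGROW
        assert state[1, 0] == AllocState.REGROW

    def test_bad_option(self):
        grid = make_grid([[P]])
        with pytest.raises(ValueError):
            plan_revegetation(make_sub([[True]], grid), grid, "X")


class TestNpcd:
    def test_small_window_count(self):
        lc = np.array([[P, P, P], [P, M, N], [P, P, N]])
        grid = make_grid(lc)
        npcd = compute_npcd(grid, window=3)
        assert npcd[1, 1] == 6  # six pure neighbours of the mosaic centre

    def test_full_field_interior(self):
        grid = make_grid(np.full((15, 15), P))
        npcd = compute_npcd(grid, window=13)
        assert npcd[7, 7] == 13 * 13 - 1

    def test_isolated_zero(self):
        lc = np.full((5, 5), N)
        lc[2, 2] = M
        assert compute_npcd(make_grid(lc), 3)[2, 2] == 0

    def test_even_window_errors(self):
        with pytest.raises(ValueError):
            compute_npcd(make_grid([[P]]), window=4)


class TestSwitchCrop:
    def test_hc_argmax_yield(self):
        assert switch_crop(
            {"maize": 30e6, "wheat": 20e6}, {"maize": 1, "wheat": 1}, "HC"
        ) == "maize"

    def test_hs_argmax_area(self):
        assert switch_crop(
            {"maize": 30e6, "wheat": 20e6}, {"maize": 10, "wheat": 40}, "HS"
        ) == "wheat"

    def test_tie_breaks_alphabetically(self):
        assert switch_crop(
            {"wheat": 5.0, "maize": 5.0}, {}, "HC"
        ) == "maize"

    def test_no_candidates_errors(self):
        with pytest.raises(ValueError):
            switch_crop({}, {}, "HC")
        with pytest.raises(ValueError):
            switch_crop({"wheat": 0.0}, {"wheat": 0.0}, "HS")


class TestEligibility:
    def test_intensification_exclusions(self):
        cfg = ScenarioConfig()
        grid = make_grid(
            np.full((1, 5), M),
            elevation=np.array([[900.0, 300, 300, 300, 300]]),
            degradation=np.array([[0, 2, 0, 0, 0]], dtype=np.int8),
            biodiv=np.array([[False, False, True, False, False]]),
            water=np.array([[False, False, False, True, False]]),
        )
        el = eligibility_mask("I", grid, cfg)
        assert el.tolist() == [[False, False, False, False, True]]

    def test_extensification_no_exclusions(self):
        cfg = ScenarioConfig()
        grid = make_grid(
            np.full((1, 2), P), biodiv=True, water=True, degradation=5
        )
        assert eligibility_mask("E", grid, cfg).all()

    def test_exclude_mask_applies(self):
        cfg = ScenarioConfig()
        grid = make_grid(np.full((1, 2), P))
        ex = np.array([[True, False]])
        assert eligibility_mask("E", grid, cfg, exclude=ex).tolist() == [
            [False, True]
        ]


class TestPixelNetGain:
    def test_intensify_doubles_cultivated_half(self, crop_meta):
        grid = make_grid([[M]], coarse_factor=1)
        cur = 1000.0
        cy = cur / (0.5 * 9.0)  # switched yield equals current per-ha
        pix = single_crop_pix(grid, crop_meta, cur)
        gain, _ = pixel_net_gain(pix, grid, "I", np.array([cy]))
        assert gain[0, 0] == pytest.approx(cur, rel=1e-12)

    def test_extensify_same_crop_halves(self, crop_meta):
        grid = make_grid([[P]], coarse_factor=1)
        cur = 1000.0
        cy = cur / 9.0
        pix = single_crop_pix(grid, crop_meta, cur)
        gain, _ = pixel_net_gain(pix, grid, "E", np.array([cy]))
        assert gain[0, 0] == pytest.approx(-0.5 * cur, rel=1e-12)

    def test_extensify_omega_and_high_yield_crop(self, crop_meta):
        grid = make_grid([[P]], coarse_factor=1)
        cur = 1000.0
        pix = single_crop_pix(grid, crop_meta, cur)
        pix.omega_layer = np.full((1, 1), 0.095)
        cy = 2.2 * cur / 9.0
        gain, _ = pixel_net_gain(pix, grid, "E", np.array([cy]))
        assert gain[0, 0] == pytest.approx(
            cur * (0.5 * 1.095 * 2.2 - 1.0), rel=1e-12
        )

    def test_no_candidate_loses_current(self, crop_meta):
        grid = make_grid([[M]], coarse_factor=1)
        pix = single_crop_pix(grid, crop_meta, 500.0)
        gain, _ = pixel_net_gain(pix, grid, "I", np.array([np.nan]))
        assert gain[0, 0] == pytest.approx(-500.0)

    def test_harvest_rate_scales_switched_only(self, crop_meta):
        grid = make_grid([[M]], coarse_factor=1)
        cur = 1000.0
        cy = cur / (0.5 * 9.0)
        pix = single_crop_pix(grid, crop_meta, cur)
        g_full, _ = pixel_net_gain(pix, grid, "I", np.array([cy]), 1.0)
        g_80, _ = pixel_net_gain(pix, grid, "I", np.array([cy]), 0.8)
        assert g_80[0, 0] == pytest.approx(0.8 * 2 * cur - cur, rel=1e-12)
        assert g_full[0, 0] > g_80[0, 0]


class TestRanking:
    def test_npcd_primary_over_gain(self):
        cfg = ScenarioConfig()
        grid = make_grid(np.full((1, 2), M))
        npcd = np.array([[10, 3]])
        gains = np.array([[1.0, 100.0]])
        ranked = rank_candidates(
            "I", grid, npcd, gains, np.ones((1, 2), bool), cfg
        )
        assert list(ranked) == [0, 1]

    def test_extensification_tiers_dominate(self):
        cfg = ScenarioConfig()
        biodiv = np.array([[True, False]])
        deg = np.array([[0, 3]], dtype=np.int8)
        grid = make_grid(np.full((1, 2), P), biodiv=biodiv, degradation=deg)
        npcd = np.array([[0, 99]])
        gains = np.array([[1.0, 100.0]])
        ranked = rank_candidates(
            "E", grid, npcd, gains, np.ones((1, 2), bool), cfg
        )
        assert list(ranked) == [0, 1]  # tier 5 (B) before tier 7 (D)

    def test_tie_breaks_row_major(self):
        cfg = ScenarioConfig()
        grid = make_grid(np.full((2, 2), M))
        npcd = np.full((2, 2), 4)
        gains = np.full((2, 2), 7.0)
        ranked = rank_candidates(
            "I", grid, npcd, gains, np.ones((2, 2), bool), cfg
        )
        assert list(ranked) == [0, 1, 2, 3]

    def test_nonpositive_gains_dropped(self):
        cfg = ScenarioConfig()
        grid = make_grid(np.full((1, 3), M))
        npcd = np.zeros((1, 3), int)
        gains = np.array([[5.0, 0.0, -2.0]])
        ranked = rank_candidates(
            "I", grid, npcd, gains, np.ones((1, 3), bool), cfg
        )
        assert list(ranked) == [0]


class TestAllocate:
    def test_greedy_prefix_overshoot(self):
        n, share = allocate_until_compensated(
            np.array([60.0, 50.0, 40.0]), 100.0
        )
        assert n == 2
        assert share == pytest.approx(1.10)

    def test_exhaustion_reports_honest_share(self):
        n, share = allocate_until_compensated(
            np.array([50.0, 41.1]), 100.0
        )
        assert n == 2
        assert share == pytest.approx(0.911)

    def test_zero_deficit_selects_nothing(self):
        n, share = allocate_until_compensated(np.array([5.0]), 0.0)
        assert (n, share) == (0, 1.0)

    def test_no_candidates(self):
        n, share = allocate_until_compensated(np.array([]), 10.0)
        assert (n, share) == (0, 0.0)

    def test_negative_deficit_errors(self):
        with pytest.raises(ValueError):
            allocate_until_compensated(np.array([1.0]), -1.0)


class TestGreedyOracle:
    """Greedy allocation equals the brute-force minimal prefix of the
    stated lexicographic order on enumerated 5x5 instances."""

    def oracle(self, mode, tier, npcd, gains, eligible, deficit):
        items = [
            (
                (tier.ravel()[i],) if mode == "E" else ()
            )
            + (-npcd.ravel()[i], -gains.ravel()[i], i)
            for i in np.flatnonzero(eligible.ravel())
            if gains.ravel()[i] > 0
        ]
        items.sort()
        chosen, cum = [], 0.0
        for it in items:
            if deficit > 0 and cum < deficit:
                chosen.append(it[-1])
                cum += gains.ravel()[it[-1]]
        share = 1.0 if deficit == 0 else (
            cum / deficit if deficit else 0.0
        )
        if deficit > 0 and not items:
            share = 0.0
        return chosen, share

    @pytest.mark.parametrize("mode", ["I", "E"])
    def test_matches_oracle_on_random_instances(self, mode):
        cfg = ScenarioConfig()
        rng = np.random.default_rng(42)
        lc = np.full((5, 5), M if mode == "I" else P)
        for trial in range(150):
            biodiv = rng.random((5, 5)) < 0.4
            water = rng.random((5, 5)) < 0.3
            deg = (rng.random((5, 5)) < 0.4) * 3
            grid = make_grid(
                lc, biodiv=biodiv, water=water,
                degradation=deg.astype(np.int8),
            )
            npcd = rng.integers(0, 3, (5, 5))
            gains = rng.integers(-1, 3, (5, 5)).astype(float)
            eligible = rng.random((5, 5)) < 0.8
            deficit = float(rng.integers(0, 8))
            ranked = rank_candidates(mode, grid, npcd, gains, eligible, cfg)
            n_sel, share = allocate_until_compensated(
                gains.ravel()[ranked], deficit
            )
            from nexusland.scenarios import _extensification_tiers

            tier = _extensification_tiers(grid, cfg)
            want_sel, want_share = self.oracle(
                mode, tier, npcd, gains, eligible, deficit
            )
            assert list(ranked[:n_sel]) == want_sel
            assert share == pytest.approx(want_share)


class TestRunScenario:
    def test_zero_suboptimal_all_unchanged(self, landscape, prepared):
        grid, table, _ = landscape
        cfg, _, omega, pix = prepared
        empty = make_sub(np.zeros(grid.shape, bool), grid)
        alloc = run_scenario(cfg, grid, pix, empty)
        assert (alloc.state == AllocState.UNCHANGED).all()
        assert alloc.compensation_share == 1.0

    def test_state_partition_and_validity(self, landscape, prepared):
        grid, table, _ = landscape
        cfg, sub, omega, pix = prepared
        alloc = run_scenario(cfg, grid, pix, sub)
        alloc.validate(grid, sub)
        total = sum(alloc.areas_ha.values())
        assert total == pytest.approx(
            grid.shape[0] * grid.shape[1] * grid.pixel_area_ha
        )

    def test_larger_eligible_set_never_decreases_share(
        self, landscape, prepared
    ):
        grid, table, _ = landscape
        cfg, sub, omega, pix = prepared
        tight = cfg.replace(use_mode="I", switch_strategy="HS")
        loose = tight.replace(degradation_risk_min=13)
        share_tight = run_scenario(
            tight, grid, pix, sub
        ).compensation_share
        share_loose = run_scenario(
            loose, grid, pix, sub
        ).compensation_share
        assert share_loose >= share_tight

    def test_mosaic_all_constrained_reports_small_share(
        self, crop_meta
    ):
        lc = np.array([[M, M], [P, P]], dtype=np.int8)
        grid = make_grid(lc, biodiv=True, coarse_factor=1)
        pix = single_crop_pix(grid, crop_meta, 100.0)
        sub = make_sub(np.array([[False, False], [False, True]]), grid)
        cfg = ScenarioConfig(use_mode="I")
        alloc = run_scenario(cfg, grid, pix, sub)
        assert not alloc.mask(AllocState.INTENSIFY).any()
        assert alloc.compensation_share < 1.0
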