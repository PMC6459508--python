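"""PA effectiveness, guild-threshold stability, classification overlays."""

import numpy as np
import pytest

from stacksdm.conservation import (CLASS_DEFORESTED,
                                   CLASS_INTACT_UNPROTECTED,
                                   CLASS_PROTECTED, classify_stable_cells,
                                   downscale_deforestation,
                                   guild_threshold_mask, pa_effectiveness,
                                   stability_map, stable_area_sweep)


def _binary(shape, cells):
    m = np.zeros(shape, dtype=np.uint8)
    for r, c in cells:
        m[r, c] = 1
    return m


@pytest.fixture(scope="module")
def pa_ids():
    # 6x6 grid, two PA blocks: block 1 = rows 0-1 x cols 0-1,
    # block 2 = rows 4-5 x cols 4-5
    ids = np.zeros((6, 6), dtype=int)
    ids[0:2, 0:2] = 1
    ids[4:6, 4:6] = 2
    return ids


class TestPaEffectiveness:
    def test_identical_future_means_zero_loss(self, pa_ids):
        cur = _binary((6, 6), [(0, 0), (5, 5)])
        maps = {"sp1": {"current": cur, "f": cur.copy()}}
        rep = pa_effectiveness(maps, pa_ids)
        assert (rep.percent_lost == 0).all()
        assert (rep.lost == 0).all()

    def test_global_extinction_lost_everywhere_it_occurred(self, pa_ids):
        cur = _binary((6, 6), [(0, 0), (4, 4)])
        maps = {"sp1": {"current": cur, "f": np.zeros((6, 6), np.uint8)}}
        rep = pa_effectiveness(maps, pa_ids)
        assert (rep.lost == 1).all()
        assert (rep.percent_lost == 100.0).all()

    def test_five_species_two_pa_hand_enumeration(self, pa_ids):
        # hand-built configuration: presence in (block1, block2) by scenario
        # sp1: (1,1) -> (1,0)   lost from block2
        # sp2: (1,0) -> (0,0)   lost from block1
        # sp3: (0,1) -> (1,1)   gained in block1, retained in block2
        # sp4: (1,1) -> (1,1)   retained everywhere
        # sp5: (0,0) -> (0,1)   gained in block2
        def sp(cur_blocks, fut_blocks):
            cells = {1: (0, 0), 2: (5, 5)}
            return {"current": _binary((6, 6),
                                       [cells[b] for b in cur_blocks]),
                    "f": _binary((6, 6), [cells[b] for b in fut_blocks])}
        maps = {"sp1": sp([1, 2], [1]), "sp2": sp([1], []),
                "sp3": sp([2], [1, 2]), "sp4": sp([1, 2], [1, 2]),
                "sp5": sp([], [2])}
        rep = pa_effectiveness(maps, pa_ids).set_index("pa_block")
        b1, b2 = rep.loc[1], rep.loc[2]
        assert (b1.current_richness, b1.lost, b1.retained, b1.gained) \
            == (3, 1, 2, 1)
        assert (b2.current_richness, b2.lost, b2.retained, b2.gained) \
            == (3, 1, 2, 1)
        assert b1.percent_lost == pytest.approx(100 / 3)

    def test_closure_lost_plus_retained_equals_current(self, pa_ids):
        rng = np.random.default_rng(4)
        maps = {}
        for i in range(12):
            maps[f"sp{i}"] = {
                "current": (rng.uniform(size=(6, 6)) > 0.5).astype(np.uint8),
                "f1": (rng.uniform(size=(6, 6)) > 0.5).astype(np.uint8),
                "f2": (rng.uniform(size=(6, 6)) > 0.6).astype(np.uint8)}
        rep = pa_effectiveness(maps, pa_ids)
        assert ((rep.lost + rep.retained) == rep.current_richness).all()

    def test_no_blocks_rejected(self):
        with pytest.raises(ValueError):
            pa_effectiveness({"sp": {"current": np.zeros((3, 3))}},
                             np.zeros((3, 3), dtype=int))


class TestGuildThresholdMask:
    def test_zero_threshold_qualifies_all_cells(self):
        rich = {"FR": np.zeros((3, 3), int), "IN": np.ones((3, 3), int)}
        mask = guild_threshold_mask(rich, {"FR": 5, "IN": 5}, 0.0)
        assert mask.all()

    def test_absent_guild_blocks_everything(self):
        rich = {"FR": np.zeros((3, 3), int), "IN": np.full((3, 3), 5)}
        mask = guild_threshold_mask(rich, {"FR": 5, "IN": 5}, 20.0)
        assert not mask.any()

    def test_toy_grid_against_hand_check_with_ceiling(self):
        # 3 guilds with totals 5/3/4; X = 30% needs ceil(1.5)=2, ceil(0.9)=1
        # and ceil(1.2)=2 species respectively
        fr = np.array([[2, 1], [3, 2]])
        in_ = np.array([[1, 1], [0, 3]])
        ne = np.array([[2, 2], [1, 4]])
        mask = guild_threshold_mask({"FR": fr, "IN": in_, "NE": ne},
                                    {"FR": 5, "IN": 3, "NE": 4}, 30.0)
        expected = np.array([[True, False], [False, True]])
        np.testing.assert_array_equal(mask, expected)

    def test_empty_guild_total_rejected(self):
        with pytest.raises(ValueError):
            guild_threshold_mask({"FR": np.ones((2, 2), int)}, {"FR": 0}, 20)


class TestStabilityMap:
    def test_seven_of_seven_is_stable(self):
        masks = [np.ones((2, 2), bool)] * 7
        counts, stable = stability_map(masks)
        assert np.all(counts == 7) and stable.all()

    def test_five_of_seven_is_not_stable(self):
        masks = [np.ones((2, 2), bool)] * 5 + [np.zeros((2, 2), bool)] * 2
        _, stable = stability_map(masks)
        assert not stable.any()

    def test_six_of_seven_is_stable(self):
        masks = [np.ones((2, 2), bool)] * 6 + [np.zeros((2, 2), bool)]
        _, stable = stability_map(masks)
        assert stable.all()

    def test_counts_equal_direct_summation(self):
        rng = np.random.default_rng(5)
        masks = [rng.uniform(size=(4, 4)) > 0.5 for _ in range(7)]
        counts, _ = stability_map(masks)
        np.testing.assert_array_equal(counts, np.sum(masks, axis=0))

    def test_wrong_scenario_count_rejected(self):
        with pytest.raises(ValueError):
            stability_map([np.ones((2, 2), bool)] * 6)


class TestClassification:
    def test_protected_takes_precedence_over_deforested(self):
        stable = np.ones((2, 2), bool)
        pa = np.array([[True, False], [False, False]])
        defo = np.array([[True, True], [False, False]])
        cls, areas = classify_stable_cells(stable, pa, defo)
        assert cls[0, 0] == CLASS_PROTECTED
        assert cls[0, 1] == CLASS_DEFORESTED
        assert cls[1, 0] == CLASS_INTACT_UNPROTECTED

    def test_no_deforestation_gives_zero_deforested_area(self):
        stable = np.ones((3, 3), bool)
        cls, areas = classify_stable_cells(stable, np.zeros((3, 3), bool),
                                           np.zeros((3, 3), bool))
        assert areas["deforested_km2"] == 0.0

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(6)
        stable = rng.uniform(size=(8, 8)) > 0.4
        pa = rng.uniform(size=(8, 8)) > 0.6
        defo = rng.uniform(size=(8, 8)) > 0.7
        cls, areas = classify_stable_cells(stable, pa, defo)
        assert areas["protected_km2"] + areas["intact_unprotected_km2"] \
            + areas["deforested_km2"] == areas["stable_total_km2"]
        assert np.all((cls > 0) == stable)


class TestDownscale:
    def test_fully_deforested_block_flags_coarse_cell(self):
        fine = np.ones((4, 4), bool)
        coarse = downscale_deforestation(fine, factor=4)
        assert coarse.shape == (1, 1) and coarse[0, 0]

    def test_boundary_fraction_below_rule_not_flagged(self):
        # 49 of 100 fine cells deforested at rule 0.5 -> not deforested
        fine = np.zeros((10, 10), bool)
        fine.ravel()[:49] = True
        assert not downscale_deforestation(fine, factor=10)[0, 0]
        fine.ravel()[49] = True  # 50/100 meets the rule
        assert downscale_deforestation(fine, factor=10)[0, 0]

    def test_random_mask_matches_block_fractions(self):
        rng = np.random.default_rng(7)
        fine = rng.uniform(size=(12, 12)) > 0.5
        coarse = downscale_deforestation(fine, factor=3)
        for i in range(4):
            for j in range(4):
                frac = fine[3 * i:3 * i + 3, 3 * j:3 * j + 3].mean()
                assert coarse[i, j] == (frac >= 0.5)

    def test_non_nesting_grid_rejected(self):
        with pytest.raises(ValueError):
            downscale_deforestation(np.zeros((10, 10), bool), factor=3)


class TestStableAreaSweep:
    def test_stable_area_non_increasing_in_threshold(self):
        rng = np.random.default_rng(8)
        scen = {}
        totals = {"FR": 6, "IN": 5, "NE": 4, "OT": 5}
        for s in [f"s{i}" for i in range(7)]:
            scen[s] = {g: rng.integers(0, t + 1, size=(10, 10))
                       for g, t in totals.items()}
        res = stable_area_sweep(scen, totals, np.zeros((10, 10), bool),
                                np.zeros((10, 10), bool))
        areas = res.stable_area_km2
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_class_areas_partition_stable_total(self):
        rng = np.random.default_rng(9)
        totals = {"FR": 4, "IN": 4}
        scen = {f"s{i}": {g: rng.integers(0, 5, size=(8, 8))
                          for g in totals} for i in range(7)}
        pa = rng.uniform(size=(8, 8)) > 0.7
        defo = rng.uniform(size=(8, 8)) > 0.8
        res = stable_area_sweep(scen, totals, pa, defo)
        for areas in res.class_areas:
            assert areas["protected_km2"] + areas["deforested_km2"] \
                + areas["intact_unprotected_km2"] \
                == areas["stable_total_km2"]
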