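import numpy as np
import pandas as pd
import pytest

from frostmap.io import GridSpec
from frostmap.sasc import (EARTH_RADIUS_M, M2_PER_MU, build_pixel_table,
                           hectares_to_mu, mu_to_hectares, pixel_area_mu,
                           score_pixels, select_affected, selection_mask)


class TestScorePixels:
    @pytest.mark.parametrize("sfdi,score", [
        (16.0, 1), (40.0, 1), (15.0, 2), (15.9, 2), (2.0, 15),
        (1.0, 16), (1.99, 16), (0.99, 0), (0.0, 0), (-3.0, 0),
    ])
    def test_score_table(self, sfdi, score):
        assert score_pixels(np.array([sfdi]))[0] == score

    def test_nodata_unscored(self):
        assert score_pixels(np.array([np.nan]))[0] == 0

    def test_scores_decrease_as_sfdi_increases(self):
        sfdi = np.arange(1.0, 20.0, 0.5)
        scores = score_pixels(sfdi)
        assert np.all(np.diff(scores) <= 0)
        assert set(scores) <= set(range(1, 17))


def table_from_classes(class_areas: dict[int, float]) -> pd.DataFrame:
    """One pixel per class, crop fraction 1, pixel_area = class area."""
    rows = []
    for score, area in class_areas.items():
        rows.append({"row": 0, "col": score, "sfdi": 17.0 - score,
                     "crop_fraction": 1.0, "pixel_area": area,
                     "score": score, "selected": False})
    return pd.DataFrame(rows)


class TestSelectAffected:
    def test_single_pixel_exact_match(self):
        table = table_from_classes({1: 375.0})
        result, out = select_affected(table, 375.0)
        assert result.residual == 0.0
        assert result.n_pixels_selected == 1
        assert out["selected"].all()

    def test_worked_example_three_classes(self):
        # areas [100, 50, 30], target 140: classes {1, 2} give |150-140| = 10,
        # beating 40 (class 1 only) and 40 (all three)
        result, _ = select_affected(table_from_classes({1: 100, 2: 50, 3: 30}), 140)
        assert result.cutoff_score == 2
        assert result.selected_area == pytest.approx(150)

    def test_matches_exhaustive_prefix_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(25):
            sfdi = rng.uniform(0, 20, (32, 32))
            frac = rng.uniform(0, 1, (32, 32))
            table = build_pixel_table(sfdi, frac, 375.0)
            scored = table[table["score"] >= 1]
            target = float(rng.uniform(
                1, (scored["crop_fraction"] * scored["pixel_area"]).sum() * 1.2))
            result, _ = select_affected(table, target)
            # oracle: enumerate every whole-class cutoff, including empty
            best = abs(0.0 - target)
            for cutoff in range(1, 17):
                sub = scored[scored["score"] <= cutoff]
                area = float((sub["crop_fraction"] * sub["pixel_area"]).sum())
                best = min(best, abs(area - target))
            assert abs(result.residual) == pytest.approx(best, abs=1e-9)

    def test_cumulative_area_monotone_in_cutoff(self):
        rng = np.random.default_rng(21)
        table = build_pixel_table(rng.uniform(0, 20, (16, 16)),
                                  rng.uniform(0, 1, (16, 16)), 375.0)
        scored = table[table["score"] >= 1]
        areas = [float((scored[scored["score"] <= s]["crop_fraction"]
                        * scored[scored["score"] <= s]["pixel_area"]).sum())
                 for s in range(1, 17)]
        assert np.all(np.diff(areas) >= 0)

    def test_selected_scores_never_exceed_unselected(self):
        rng = np.random.default_rng(22)
        table = build_pixel_table(rng.uniform(0, 20, (16, 16)),
                                  rng.uniform(0.2, 1, (16, 16)), 375.0)
        _, out = select_affected(table, 20000.0)
        sel = out[out["selected"]]
        unsel = out[(~out["selected"]) & (out["score"] >= 1)]
        if not sel.empty and not unsel.empty:
            assert sel["score"].max() <= unsel["score"].min()

    def test_rerun_is_bit_identical(self):
        rng = np.random.default_rng(23)
        table = build_pixel_table(rng.uniform(0, 20, (8, 8)),
                                  rng.uniform(0, 1, (8, 8)), 375.0)
        r1, t1 = select_affected(table, 5000.0)
        r2, t2 = select_affected(table, 5000.0)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)

    def test_target_above_total_selects_all_with_warning(self):
        table = table_from_classes({1: 100, 2: 50})
        with pytest.warns(UserWarning, match="below the target"):
            result, out = select_affected(table, 1000.0)
        assert result.selected_area == pytest.approx(150)
        assert out["selected"].all()

    def test_no_scored_pixels_raises(self):
        table = build_pixel_table(np.full((3, 3), 0.5), np.ones((3, 3)), 375.0)
        with pytest.raises(ValueError, match="no scored pixels"):
            select_affected(table, 100.0)

    def test_nonpositive_target_raises(self):
        with pytest.raises(ValueError, match="positive"):
            select_affected(table_from_classes({1: 10}), 0.0)

    def test_within_class_refinement_never_worse(self):
        rng = np.random.default_rng(24)
        for _ in range(10):
            table = build_pixel_table(rng.uniform(0, 20, (12, 12)),
                                      rng.uniform(0, 1, (12, 12)), 375.0)
            target = float(rng.uniform(1000, 20000))
            coarse, _ = select_affected(table, target)
            fine, _ = select_affected(table, target, within_class=True)
            assert abs(fine.residual) <= abs(coarse.residual) + 1e-9

    def test_selection_mask_round_trip(self):
        table = table_from_classes({1: 100})
        _, out = select_affected(table, 100.0)
        mask = selection_mask(out, (1, 4))
        assert mask[0, 1] == 1 and mask.sum() == 1


class TestBuildPixelTable:
    def test_drops_nodata_and_zero_fraction(self):
        sfdi = np.array([[1.5, np.nan], [2.5, 3.5]])
        frac = np.array([[0.5, 0.5], [0.0, 1.0]])
        table = build_pixel_table(sfdi, frac, 375.0)
        assert len(table) == 2
        assert set(zip(table["row"], table["col"])) == {(0, 0), (1, 1)}

    def test_fraction_out_of_range_raises(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            build_pixel_table(np.ones((2, 2)), np.full((2, 2), 1.5), 375.0)


class TestPixelArea:
    def test_500m_pixel_is_375_mu(self):
        grid = GridSpec(pixel_width=500.0, pixel_height=500.0)
        assert pixel_area_mu(grid) == pytest.approx(375.0, abs=0.01)

    def test_one_square_metre(self):
        grid = GridSpec(pixel_width=1.0, pixel_height=1.0)
        assert pixel_area_mu(grid) == pytest.approx(0.0015, abs=1e-6)

    def test_geographic_cell_matches_spherical_integration_oracle(self):
        # independent oracle: numerically integrate R^2 cos(lat) dlat dlon
        grid = GridSpec(pixel_width=0.005, pixel_height=0.005, crs="geographic")
        for lat in (0.0, 36.0, 60.0):
            got = pixel_area_mu(grid, latitude=lat)
            lats = np.linspace(np.radians(lat - 0.0025), np.radians(lat + 0.0025), 2001)
            strip = np.trapezoid(np.cos(lats), lats)
            oracle = EARTH_RADIUS_M ** 2 * np.radians(0.005) * strip / M2_PER_MU
            assert got == pytest.approx(oracle, rel=1e-3)

    def test_geographic_without_latitude_raises(self):
        with pytest.raises(ValueError, match="latitude"):
            pixel_area_mu(GridSpec(crs="geographic"))

    def test_degenerate_transform_raises(self):
        with pytest.raises(ValueError):
            GridSpec(pixel_width=0.0)

    def test_mu_hectare_round_trip(self):
        assert hectares_to_mu(mu_to_hectares(375.0)) == pytest.approx(375.0)
        assert mu_to_hectares(15.0) == pytest.approx(1.0)
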