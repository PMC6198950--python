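"""Centroid detection, placement statistics, cycle times, Fisher comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from sstembatch import (
    ApertureGrid,
    cycle_time_statistics,
    detect_section_centroids,
    fisher_exact_yield_comparison,
    placement_statistics,
)
from sstembatch.exceptions import ParameterError
from sstembatch.synthetic import render_placement_frame

GRID = ApertureGrid(rows=2, cols=3, origin=(1.9, 1.9))


def centroid_frame(records):
    df = pd.DataFrame(records, columns=["section_id", "row", "col", "dx_um", "dy_um", "fragment"])
    return df, render_placement_frame(df, GRID, scale=10.0)


class TestDetectCentroids:
    def test_centered_square_has_zero_offset(self):
        df, frame = centroid_frame([(0, 0, 0, 0.0, 0.0, False)])
        det = detect_section_centroids(frame, GRID, scale=10.0, intensity_threshold=100)
        assert len(det) == 1
        assert abs(det.dx_um[0]) <= 5.0 and abs(det.dy_um[0]) <= 5.0  # 0.5 px * 10 um/px

    def test_translation_equivariance(self):
        df, frame = centroid_frame([(0, 0, 1, 80.0, 0.0, False)])
        det = detect_section_centroids(frame, GRID, scale=10.0, intensity_threshold=100)
        assert det.dx_um[0] == pytest.approx(80.0, abs=5.0)
        assert det.dy_um[0] == pytest.approx(0.0, abs=5.0)

    def test_fragmented_aperture_flagged(self):
        df, frame = centroid_frame([(0, 0, 0, np.nan, np.nan, True), (1, 1, 2, -50.0, 120.0, False)])
        det = detect_section_centroids(frame, GRID, scale=10.0, intensity_threshold=100)
        frag = det[det.fragment]
        assert len(frag) == 2  # both pieces flagged
        assert frag[["dx_um", "dy_um"]].isna().all().all()
        good = det[~det.fragment]
        assert good.dx_um.iloc[0] == pytest.approx(-50.0, abs=5.0)

    def test_empty_frame_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            det = detect_section_centroids(np.zeros((50, 50)), GRID, 10.0, intensity_threshold=10)
        assert len(det) == 0

    def test_bad_scale_rejected(self):
        with pytest.raises(ParameterError):
            detect_section_centroids(np.zeros((10, 10)), GRID, scale=0.0, intensity_threshold=1)

    def test_noiseless_recovery_within_half_pixel(self):
        offsets = [(0, 0, 0, 40.0, -30.0, False), (1, 0, 2, -120.0, 60.0, False),
                   (2, 1, 1, 0.0, 200.0, False)]
        df, frame = centroid_frame(offsets)
        det = detect_section_centroids(frame, GRID, scale=10.0, intensity_threshold=100)
        merged = det.merge(df, on=["row", "col"], suffixes=("_det", "_true"))
        assert len(merged) == 3
        assert (merged.dx_um_det - merged.dx_um_true).abs().max() <= 5.0
        assert (merged.dy_um_det - merged.dy_um_true).abs().max() <= 5.0


def make_centroids(dx, dy, fragment=None):
    n = len(dx)
    return pd.DataFrame(
        {
            "section_id": range(n),
            "row": 0,
            "col": 0,
            "dx_um": dx,
            "dy_um": dy,
            "fragment": fragment if fragment is not None else [False] * n,
        }
    )


class TestPlacementStatistics:
    def test_perfectly_centered(self):
        stats = placement_statistics(make_centroids([0.0] * 4, [0.0] * 4), 1.0, GRID)
        assert (stats.mean_x, stats.sd_x, stats.fraction_contained) == (0.0, 0.0, 1.0)

    def test_containment_boundary_geometry(self):
        # 1.0 mm section in a 1.4 mm aperture -> +/- 200 um bound
        stats = placement_statistics(make_centroids([190.0, 250.0], [0.0, 0.0]), 1.0, GRID)
        assert (stats.n_contained, stats.n_partial) == (1, 1)
        assert stats.fraction_contained == 0.5

    def test_translation_equivariance(self):
        dx = [10.0, -40.0, 25.0, 5.0]
        dy = [0.0, 30.0, -10.0, 70.0]
        s0 = placement_statistics(make_centroids(dx, dy), 1.0, GRID)
        s1 = placement_statistics(
            make_centroids([v + 17.0 for v in dx], [v - 8.0 for v in dy]), 1.0, GRID
        )
        assert s1.mean_x == pytest.approx(s0.mean_x + 17.0)
        assert s1.mean_y == pytest.approx(s0.mean_y - 8.0)
        assert s1.sd_x == pytest.approx(s0.sd_x)
        assert s1.sd_y == pytest.approx(s0.sd_y)

    def test_containment_monotone_in_aperture_size(self):
        rng = np.random.default_rng(0)
        df = make_centroids(rng.normal(-20, 110, 200), rng.normal(60, 150, 200))
        fractions = []
        for side in (1.4, 2.0, 3.0):
            grid = ApertureGrid(aperture_side=side, pitch_x=3.2, pitch_y=3.2)
            fractions.append(placement_statistics(df, 1.0, grid).fraction_contained)
        assert fractions[0] <= fractions[1] <= fractions[2]

    def test_fragments_excluded_but_counted(self):
        df = make_centroids([0.0, np.nan, 100.0], [0.0, np.nan, 0.0], [False, True, False])
        stats = placement_statistics(df, 1.0, GRID)
        assert stats.n_analyzed == 2
        assert stats.n_excluded_fragments == 1
        assert stats.mean_x == pytest.approx(50.0)

    def test_all_fragments_rejected(self):
        df = make_centroids([np.nan], [np.nan], [True])
        with pytest.raises(ParameterError):
            placement_statistics(df, 1.0, GRID)


class TestCycleTimes:
    def test_published_style_means_give_dry_down(self):
        log = pd.DataFrame(
            {"section_id": [0, 1], "pickup_s": [18.9, 18.9], "cycle_s": [43.5, 43.5]}
        )
        stats = cycle_time_statistics(log)
        assert stats["dry_down_estimate_s"] == pytest.approx(24.6)

    def test_constant_log(self):
        log = pd.DataFrame({"section_id": range(10), "pickup_s": [15.0] * 10, "cycle_s": [40.0] * 10})
        stats = cycle_time_statistics(log)
        assert stats["sd_pickup_s"] == stats["sd_cycle_s"] == 0.0
        assert stats["dry_down_estimate_s"] == pytest.approx(25.0)

    def test_single_entry_sd_zero(self):
        stats = cycle_time_statistics(
            pd.DataFrame({"section_id": [0], "pickup_s": [10.0], "cycle_s": [30.0]})
        )
        assert stats["sd_cycle_s"] == 0.0

    def test_invalid_rows_listed(self):
        log = pd.DataFrame({"section_id": [0, 1], "pickup_s": [50.0, 10.0], "cycle_s": [40.0, 40.0]})
        with pytest.raises(ParameterError, match=r"\[0\]"):
            cycle_time_statistics(log)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            cycle_time_statistics(pd.DataFrame(columns=["section_id", "pickup_s", "cycle_s"]))


class TestFisher:
    def test_published_comparison_is_significant(self):
        res = fisher_exact_yield_comparison([[727, 2], [3649, 51]])
        assert res.p_one_sided < 0.05
        assert res.p_two_sided < 0.05

    def test_one_sided_matches_hypergeometric_enumeration(self):
        # independent oracle: collected-in-A ~ Hypergeom(N, K=collected total,
        # n=row-A total); one-sided p = P(X >= observed)
        a, b, c, d = 727, 2, 3649, 51
        res = fisher_exact_yield_comparison([[a, b], [c, d]])
        N, K, n_row = a + b + c + d, a + c, a + b
        p_oracle = hypergeom(N, K, n_row).pmf(np.arange(a, min(K, n_row) + 1)).sum()
        assert res.p_one_sided == pytest.approx(p_oracle, rel=1e-9)

    def test_no_association(self):
        res = fisher_exact_yield_comparison([[1, 1], [1, 1]])
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_extreme_small_table_tail(self):
        # method A collected both, method B lost both: most extreme table in
        # the direction of the alternative, point probability 1/6
        res = fisher_exact_yield_comparison([[2, 0], [0, 2]])
        assert res.p_one_sided == pytest.approx(1 / 6)
        # the reversed table is maximally against the alternative
        rev = fisher_exact_yield_comparison([[0, 2], [2, 0]])
        assert rev.p_one_sided == pytest.approx(1.0)
        # two-sided p is symmetric under row swap
        assert res.p_two_sided == pytest.approx(rev.p_two_sided)

    def test_p_values_in_unit_interval(self):
        for table in ([[5, 0], [0, 5]], [[10, 3], [4, 9]], [[1, 0], [0, 1]]):
            res = fisher_exact_yield_comparison(table)
            assert 0 < res.p_one_sided <= 1
            assert 0 < res.p_two_sided <= 1

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning):
            res = fisher_exact_yield_comparison([[0, 0], [3, 4]])
        assert res.p_two_sided == 1.0

    def test_bad_table_rejected(self):
        with pytest.raises(ParameterError):
            fisher_exact_yield_comparison([[1, 2, 3], [4, 5, 6]])
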