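"""Network weighting strategies: thresholds, per-definition matrix oracles."""

import numpy as np
import pandas as pd
import pytest

from sbnfuse import (
    InvalidParameterError,
    RoiGeometry,
    build_nws,
    ed_matrix,
    length_filter,
    sd_weight,
    threshold_grid,
)
from sbnfuse.nws import NWS_NAMES, EmptyNetworkError
from sbnfuse.synthetic import TRACT_COLUMNS


def _table(rows):
    """rows: (i, j, nstr, length, wm, vol, fa, md, rd)"""
    return pd.DataFrame(
        [("s", "p", *r) for r in rows], columns=TRACT_COLUMNS)


@pytest.fixture
def toy_geometry():
    return RoiGeometry(
        roi_labels=["a", "b", "c"],
        centroids=np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0], [0.0, 0.0, 10.0]]),
        voxel_counts=np.array([10, 10, 30]),
    )


class TestThresholdGrid:
    def test_paper_grid_has_13_values(self):
        grid = threshold_grid(0.0, 6.0, 0.5)
        assert len(grid) == 13
        np.testing.assert_allclose(grid, np.arange(13) * 0.5)

    def test_degenerate_and_no_overshoot(self):
        np.testing.assert_allclose(threshold_grid(0, 0, 0.5), [0.0])
        np.testing.assert_allclose(threshold_grid(0, 1.0, 0.3), [0.0, 0.3, 0.6, 0.9])

    def test_bad_step(self):
        with pytest.raises(InvalidParameterError):
            threshold_grid(0, 6, 0)


class TestLengthFilter:
    def test_zero_threshold_is_identity(self):
        t = _table([(0, 1, 5, 10.0, 0.3, 1.0, 0.5, 1e-3, 8e-4)])
        assert length_filter(t, 0.0) is t

    def test_direct_comparison(self):
        t = _table([(0, 1, 5, 10.0, wm, 1.0, 0.5, 1e-3, 8e-4)
                    for wm in (0.3, 2.0, 5.9)])
        assert len(length_filter(t, 1.0)) == 2

    def test_sweep_yields_13_tables(self):
        t = _table([(0, 1, 5, 10.0, wm, 1.0, 0.5, 1e-3, 8e-4)
                    for wm in np.linspace(0.2, 7.0, 30)])
        tables = [length_filter(t, l) for l in threshold_grid(0, 6.0, 0.5)]
        assert len(tables) == 13
        sizes = [len(x) for x in tables]
        assert sizes == sorted(sizes, reverse=True)

    def test_negative_threshold(self):
        with pytest.raises(InvalidParameterError):
            length_filter(_table([]), -1.0)


class TestSdWeight:
    @pytest.mark.parametrize("g_i,g_j,n,expected", [
        (10, 10, 5, 0.5),
        (7, 7, 0, 0.0),
        (30, 10, 8, 0.4),
    ])
    def test_values(self, g_i, g_j, n, expected):
        assert sd_weight(g_i, g_j, n) == pytest.approx(expected)

    def test_zero_voxels(self):
        with pytest.raises(InvalidParameterError):
            sd_weight(0, 5, 1)


class TestEdMatrix:
    def test_345_triangle(self, toy_geometry):
        ed = ed_matrix(toy_geometry)
        assert ed.weights[0, 1] == pytest.approx(5.0)

    def test_identical_centroids(self):
        g = RoiGeometry(["a", "b", "c"],
                        np.array([[1.0, 1, 1], [1, 1, 1], [0, 0, 0]]),
                        np.array([5, 5, 5]))
        assert ed_matrix(g).weights[0, 1] == 0.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        c = rng.normal(size=(4, 3))
        g = RoiGeometry([f"r{i}" for i in range(4)], c, np.ones(4, dtype=int))
        ed = ed_matrix(g).weights
        for i in range(4):
            for j in range(4):
                assert ed[i, j] == pytest.approx(np.linalg.norm(c[i] - c[j]))


class TestBuildNws:
    def test_90x90(self):
        from sbnfuse import generate_roi_geometry
        g = generate_roi_geometry(90, seed=0)
        t = _table([(0, 1, 5, 30.0, 10.0, 40.0, 0.5, 1e-3, 8e-4)])
        stack = build_nws(t, g)
        assert all(stack[name].n == 90 for name in NWS_NAMES)

    def test_single_record_pstr_normalization(self, toy_geometry):
        t = _table([(0, 1, 5, 30.0, 10.0, 40.0, 0.5, 1e-3, 8e-4)])
        stack = build_nws(t, toy_geometry)
        assert stack["PSTR"].weights[0, 1] == pytest.approx(1.0)
        assert np.triu(stack["PSTR"].weights, 1).sum() == pytest.approx(1.0)

    def test_three_record_hand_computation(self, toy_geometry):
        # two bundles between (0,1) plus one between (1,2)
        t = _table([
            (0, 1, 4, 20.0, 10.0, 30.0, 0.40, 1.0e-3, 8.0e-4),
            (0, 1, 6, 30.0, 12.0, 50.0, 0.60, 1.2e-3, 9.0e-4),
            (1, 2, 10, 50.0, 40.0, 90.0, 0.50, 0.9e-3, 7.0e-4),
        ])
        s = build_nws(t, toy_geometry)
        assert s["NSTR"].weights[0, 1] == 10
        assert s["NSTR"].weights[1, 2] == 10
        # count-weighted means: (4*20 + 6*30)/10 = 26; FA (4*.4+6*.6)/10 = .52
        assert s["ATL"].weights[0, 1] == pytest.approx(26.0)
        assert s["FA"].weights[0, 1] == pytest.approx(0.52)
        assert s["MD"].weights[0, 1] == pytest.approx(1.12e-3)
        assert s["RD"].weights[1, 2] == pytest.approx(7.0e-4)
        assert s["TV"].weights[0, 1] == pytest.approx(80.0)
        # SD: 2/(10+10)*10 = 1.0 ; 2/(10+30)*10 = 0.5
        assert s["SD"].weights[0, 1] == pytest.approx(1.0)
        assert s["SD"].weights[1, 2] == pytest.approx(0.5)
        # PSTR: total NSTR = 20
        assert s["PSTR"].weights[0, 1] == pytest.approx(0.5)
        assert s["ED"].weights[0, 1] == pytest.approx(5.0)

    def test_sd_is_elementwise_transform_of_nstr(self, small_geometry, small_cohort):
        _, tables, geoms = small_cohort
        key = ("sub-01", "scan-01")
        s = build_nws(tables[key], geoms[key])
        g = geoms[key].voxel_counts.astype(float)
        expected = 2.0 / (g[:, None] + g[None, :]) * s["NSTR"].weights
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(s["SD"].weights, expected)

    def test_filter_monotonicity(self, small_cohort):
        _, tables, geoms = small_cohort
        key = ("sub-02", "scan-01")
        prev = None
        for l_mm in threshold_grid(0, 6, 0.5):
            nstr = build_nws(tables[key], geoms[key], l_mm)["NSTR"].weights
            if prev is not None:
                assert np.all(nstr <= prev + 1e-12)
            prev = nstr

    def test_network_invariants(self, small_cohort):
        _, tables, geoms = small_cohort
        key = ("sub-01", "scan-02")
        s = build_nws(tables[key], geoms[key])
        for name in NWS_NAMES:
            w = s[name].weights
            np.testing.assert_array_equal(w, w.T)
            assert np.all(np.diag(w) == 0)
            assert np.all(w >= 0)
            assert np.all(np.isfinite(w))

    def test_empty_after_filter(self, toy_geometry):
        t = _table([(0, 1, 5, 10.0, 0.5, 1.0, 0.5, 1e-3, 8e-4)])
        with pytest.raises(EmptyNetworkError):
            build_nws(t, toy_geometry, l_mm=5.0)

    def test_roi_out_of_range(self, toy_geometry):
        t = _table([(0, 7, 5, 10.0, 5.0, 1.0, 0.5, 1e-3, 8e-4)])
        with pytest.raises(InvalidParameterError):
            build_nws(t, toy_geometry)
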