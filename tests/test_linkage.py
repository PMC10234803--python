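"""Exposure-construction operations vs brute-force and analytic oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from qgmix import reference
from qgmix.linkage import (
    CentroidSet,
    DecayParams,
    LinkageError,
    PointSourceSet,
    RoadSegmentSet,
    assemble_exposure_matrix,
    decayed_source_exposure,
    extract_grid_values,
    multi_year_mean,
    nearest_centroid_link,
    road_density,
)
from qgmix.spatial_io import Grid


def make_centroids(xy, ids=None):
    xy = np.asarray(xy, float)
    return CentroidSet(
        ids=np.asarray(ids if ids is not None else range(len(xy))),
        xy=xy,
        years=[2000],
        values={},
    )


def make_sources(rows):
    """rows: (source_id, x, y, chemical, year, mass)"""
    return PointSourceSet(
        table=pd.DataFrame(
            rows, columns=["source_id", "x", "y", "chemical", "year", "mass_lb"]
        )
    )


def make_roads(segments):
    """segments: (x1, y1, x2, y2)"""
    t = pd.DataFrame(segments, columns=["x1", "y1", "x2", "y2"])
    t.insert(0, "segment_id", np.arange(len(t)))
    t["length"] = np.hypot(t.x2 - t.x1, t.y2 - t.y1)
    return RoadSegmentSet(table=t)


class TestNearestCentroid:
    def test_coincident_point(self):
        cents = make_centroids([[0, 0], [5, 5], [9, 1]])
        idx = nearest_centroid_link(np.array([[5.0, 5.0]]), cents)
        assert idx.tolist() == [1]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(21)
        pts = rng.uniform(0, 100, (50, 2))
        cxy = rng.uniform(0, 100, (20, 2))
        cents = make_centroids(cxy)
        idx = nearest_centroid_link(pts, cents)
        d = np.linalg.norm(pts[:, None, :] - cxy[None, :, :], axis=2)
        assert (idx == d.argmin(axis=1)).all()

    def test_singleton_centroid(self):
        cents = make_centroids([[3, 3]])
        idx = nearest_centroid_link(np.random.default_rng(0).uniform(0, 9, (7, 2)),
                                    cents)
        assert (idx == 0).all()

    def test_tie_broken_by_lowest_id(self):
        # two centroids equidistant from the origin; higher id listed first
        cents = make_centroids([[1.0, 0.0], [-1.0, 0.0]], ids=[7, 3])
        idx = nearest_centroid_link(np.array([[0.0, 0.0]]), cents)
        assert cents.ids[idx[0]] == 3

    def test_empty_set_rejected(self):
        with pytest.raises(LinkageError):
            nearest_centroid_link(np.array([[0.0, 0.0]]),
                                  make_centroids(np.empty((0, 2))))


class TestExtractGridValues:
    def make_grid(self):
        vals = np.arange(12, dtype=float).reshape(3, 4)  # rows south-up
        return Grid(values=vals, xll=0.0, yll=0.0, cellsize=1.0)

    def test_constant_grid(self):
        g = Grid(values=np.full((5, 5), 2.5), xll=0, yll=0, cellsize=2.0)
        pts = np.random.default_rng(1).uniform(0, 10, (20, 2))
        assert (extract_grid_values(g, pts) == 2.5).all()

    def test_interior_edge_goes_to_higher_cell(self):
        g = self.make_grid()
        # x exactly on the boundary between columns 1 and 2
        v = extract_grid_values(g, np.array([[2.0, 0.5]]))
        assert v[0] == g.values[0, 2]

    def test_matches_index_arithmetic(self):
        g = self.make_grid()
        rng = np.random.default_rng(22)
        pts = rng.uniform(0, [4, 3], (100, 2))
        vals = extract_grid_values(g, pts)
        col = np.floor(pts[:, 0] / 1.0).astype(int)
        row = np.floor(pts[:, 1] / 1.0).astype(int)
        np.testing.assert_array_equal(vals, g.values[row, col])

    def test_outside_extent_flagged_missing(self):
        g = self.make_grid()
        v = extract_grid_values(g, np.array([[-0.5, 0.5], [1.0, 1.0]]))
        assert np.isnan(v[0]) and not np.isnan(v[1])


class TestMultiYearMean:
    def test_constant_years(self):
        assert multi_year_mean(np.full((1, 16), 4.2))[0] == pytest.approx(4.2)

    def test_arithmetic(self):
        assert multi_year_mean(np.arange(1.0, 17.0)[None, :])[0] == pytest.approx(8.5)

    def test_missing_years_excluded(self):
        vals = np.arange(1.0, 17.0)
        vals[[2, 7, 11]] = np.nan
        remaining = np.delete(np.arange(1.0, 17.0), [2, 7, 11])
        assert multi_year_mean(vals[None, :])[0] == pytest.approx(remaining.mean())

    def test_all_missing_is_nan(self):
        assert np.isnan(multi_year_mean(np.full((1, 4), np.nan))[0])


class TestDecayedSourceExposure:
    def test_no_sources_in_buffer(self):
        src = make_sources([(0, 50.0, 50.0, "benzene", 2005, 100.0)])
        out = decayed_source_exposure(np.array([[0.0, 0.0]]), src, "benzene")
        assert out[0] == 0.0

    def test_source_at_zero_distance(self):
        src = make_sources([(0, 1.0, 2.0, "toluene", 2005, 100.0)])
        out = decayed_source_exposure(np.array([[1.0, 2.0]]), src, "toluene")
        assert out[0] == pytest.approx(100.0, abs=1e-12)

    def test_hand_computed_three_source_sum(self):
        """Sources at 1, 2.5 and 4 km with masses 10, 20, 40 and decay
        range 5: the burden equals the term-by-term sum computed by an
        independent per-source loop."""
        src = make_sources(
            [
                (0, 1.0, 0.0, "xylene", 2005, 10.0),
                (1, 0.0, 2.5, "xylene", 2005, 20.0),
                (2, -4.0, 0.0, "xylene", 2005, 40.0),
            ]
        )
        out = decayed_source_exposure(
            np.array([[0.0, 0.0]]), src, "xylene", DecayParams(5.0, 5.0)
        )
        expected = 0.0
        for d, m in [(1.0, 10.0), (2.5, 20.0), (4.0, 40.0)]:
            expected += m * math.exp(-3.0 * d / 5.0)
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_sources_beyond_buffer_excluded(self):
        src = make_sources(
            [
                (0, 4.9, 0.0, "benzene", 2005, 10.0),
                (1, 5.1, 0.0, "benzene", 2005, 1000.0),
            ]
        )
        out = decayed_source_exposure(np.array([[0.0, 0.0]]), src, "benzene")
        assert out[0] == pytest.approx(10.0 * math.exp(-3 * 4.9 / 5), abs=1e-12)

    def test_masses_are_mean_annual(self):
        src = make_sources(
            [
                (0, 0.0, 0.0, "benzene", 2004, 100.0),
                (0, 0.0, 0.0, "benzene", 2005, 300.0),
            ]
        )
        out = decayed_source_exposure(np.array([[0.0, 0.0]]), src, "benzene")
        assert out[0] == pytest.approx(200.0, abs=1e-12)


class TestRoadDensity:
    def test_no_roads(self):
        out = road_density(np.array([[0.0, 0.0]]), make_roads([]), 5.0)
        assert out[0] == 0.0

    def test_contained_segment_contributes_full_length(self):
        roads = make_roads([(-1.0, 0.0, 2.0, 0.0)])
        out = road_density(np.array([[0.0, 0.0]]), roads, 5.0)
        assert out[0] == pytest.approx(3.0, abs=1e-12)

    def test_chord_length_analytic(self):
        """A long line at perpendicular offset h from the center is clipped
        to the chord 2*sqrt(r^2 - h^2)."""
        h, r = 3.0, 5.0
        roads = make_roads([(-100.0, h, 100.0, h)])
        out = road_density(np.array([[0.0, 0.0]]), roads, r)
        assert out[0] == pytest.approx(2 * math.sqrt(r * r - h * h), abs=1e-9)

    def test_matches_shapely_oracle(self):
        shapely = pytest.importorskip("shapely")
        rng = np.random.default_rng(23)
        segs = rng.uniform(-10, 10, (40, 4))
        roads = make_roads(segs)
        pts = rng.uniform(-5, 5, (10, 2))
        out = road_density(pts, roads, 4.0)
        lines = [
            shapely.LineString([(a, b), (c, d)]) for a, b, c, d in segs
        ]
        for i, (px, py) in enumerate(pts):
            disc = shapely.Point(px, py).buffer(4.0, quad_segs=512)
            expected = sum(line.intersection(disc).length for line in lines)
            assert out[i] == pytest.approx(expected, rel=1e-4)

    def test_subdivision_invariance(self):
        rng = np.random.default_rng(24)
        pts = rng.uniform(0, 10, (5, 2))
        a = np.array([1.0, 1.0])
        b = np.array([9.0, 7.0])
        whole = make_roads([(a[0], a[1], b[0], b[1])])
        ts = np.sort(np.concatenate([[0.0, 1.0], rng.random(6)]))
        pieces = [
            tuple(a + t0 * (b - a)) + tuple(a + t1 * (b - a))
            for t0, t1 in zip(ts[:-1], ts[1:])
        ]
        split = make_roads(pieces)
        np.testing.assert_allclose(
            road_density(pts, whole, 3.0), road_density(pts, split, 3.0), atol=1e-9
        )

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(LinkageError):
            road_density(np.array([[0.0, 0.0]]), make_roads([]), 0.0)


class TestAssembleExposureMatrix:
    def _columns(self, n, fill=1.0):
        return {c: np.full(n, fill) for c in reference.EXPOSURE_COLUMNS}

    def test_empty_cohort_keeps_schema(self):
        cohort = pd.DataFrame({"id": pd.Series(dtype=int)})
        mat = assemble_exposure_matrix(cohort, self._columns(0))
        assert list(mat.columns) == reference.EXPOSURE_COLUMNS
        assert len(mat) == 0

    def test_missing_values_hard_failure_lists_ids(self):
        cohort = pd.DataFrame({"id": [10, 11, 12]})
        cols = self._columns(3)
        cols["so4"][1] = np.nan
        with pytest.raises(LinkageError, match="11"):
            assemble_exposure_matrix(cohort, cols)

    def test_allow_drop_removes_rows(self):
        cohort = pd.DataFrame({"id": [10, 11, 12]})
        cols = self._columns(3)
        cols["so4"][1] = np.nan
        mat = assemble_exposure_matrix(cohort, cols, allow_drop=True)
        assert mat.index.tolist() == [10, 12]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(25)
        n = 30
        cohort = pd.DataFrame({"id": np.arange(n)})
        cols = {c: rng.normal(size=n) for c in reference.EXPOSURE_COLUMNS}
        mat = assemble_exposure_matrix(cohort, cols)
        perm = rng.permutation(n)
        mat_p = assemble_exposure_matrix(
            cohort.iloc[perm].reset_index(drop=True),
            {c: v[perm] for c, v in cols.items()},
        )
        pd.testing.assert_frame_equal(mat, mat_p.sort_index())

    def test_incomplete_columns_rejected(self):
        cohort = pd.DataFrame({"id": [0]})
        cols = self._columns(1)
        cols.pop("so4")
        with pytest.raises(LinkageError, match="so4"):
            assemble_exposure_matrix(cohort, cols)
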