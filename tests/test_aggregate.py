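"""Regional aggregation, cumulative comparisons and minimum-curvature
gridding, each checked against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from radsurvey.aggregate import (
    UNASSIGNED,
    assign_region,
    cumulative_distribution,
    fraction_direct_below,
    grid_minimum_curvature,
    summarize,
)
from radsurvey.synthetic import generate_sites

from conftest import single_region_config


TWO_BOXES = [
    ("west", Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])),
    ("east", Polygon([(2, 0), (3, 0), (3, 1), (2, 1)])),
]


def _winding_number_contains(poly_coords, x, y):
    """Independent ray-casting point-in-polygon oracle."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


class TestAssignRegion:
    def test_centroid_lands_in_its_polygon(self):
        pts = pd.DataFrame({"lat": [0.5, 0.5], "lon": [0.5, 2.5]})
        out = assign_region(pts, TWO_BOXES)
        assert out["region"].tolist() == ["west", "east"]

    def test_distant_point_flagged_unassigned(self):
        pts = pd.DataFrame({"lat": [10.0], "lon": [10.0]})
        out = assign_region(pts, TWO_BOXES, tolerance=0.1)
        assert out["region"].tolist() == [UNASSIGNED]

    def test_nearby_point_snaps_to_nearest(self):
        pts = pd.DataFrame({"lat": [0.5], "lon": [1.05]})
        out = assign_region(pts, TWO_BOXES, tolerance=0.1)
        assert out["region"].tolist() == ["west"]

    def test_labels_match_ray_casting_oracle(self, rng):
        xs = rng.uniform(-0.5, 3.5, size=1000)
        ys = rng.uniform(-0.5, 1.5, size=1000)
        pts = pd.DataFrame({"lat": ys, "lon": xs})
        out = assign_region(pts, TWO_BOXES, tolerance=0.0)
        coords = {rid: list(poly.exterior.coords)[:-1] for rid, poly in TWO_BOXES}
        for label, x, y in zip(out["region"], xs, ys):
            oracle = UNASSIGNED
            for rid, cs in coords.items():
                if _winding_number_contains(cs, x, y):
                    oracle = rid
            # boundary grazing is legitimately ambiguous
            on_edge = any(
                poly.boundary.distance(Point(x, y)) < 1e-12 for _, poly in TWO_BOXES
            )
            if not on_edge:
                assert label == oracle

    def test_empty_boundaries_rejected(self):
        with pytest.raises(ValueError):
            assign_region(pd.DataFrame({"lat": [0], "lon": [0]}), [])


class TestSummaries:
    def test_basic_statistics(self):
        df = pd.DataFrame({"region": ["a"] * 3, "v": [10.0, 20.0, 30.0]})
        out = summarize(df, "v")
        row = out.iloc[0]
        assert (row["n"], row["mean"], row["sd"]) == (3, 20.0, 10.0)
        assert (row["min"], row["max"]) == (10.0, 30.0)

    def test_single_record_group_carries_sd_sentinel(self):
        df = pd.DataFrame({"region": ["solo"], "v": [71.0]})
        out = summarize(df, "v")
        assert out.loc[0, "mean"] == 71.0
        assert np.isnan(out.loc[0, "sd"])

    def test_permutation_invariant_and_matches_streaming_oracle(self, rng):
        values = rng.uniform(0, 100, size=200)
        regions = rng.choice(["a", "b", "c"], size=200)
        df = pd.DataFrame({"region": regions, "v": values})
        perm = rng.permutation(200)
        out1 = summarize(df, "v")
        out2 = summarize(df.iloc[perm].reset_index(drop=True), "v")
        pd.testing.assert_frame_equal(out1, out2)
        # streaming one-pass oracle
        for _, row in out1.iterrows():
            sel = values[regions == row["region"]]
            n, s, s2 = 0, 0.0, 0.0
            for v in sel:
                n, s, s2 = n + 1, s + v, s2 + v * v
            assert row["n"] == n
            assert row["mean"] == pytest.approx(s / n)
            assert row["sd"] == pytest.approx(
                np.sqrt((s2 - s * s / n) / (n - 1)), rel=1e-9
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=["region", "v"]), "v")


class TestCumulative:
    def test_cdf_steps_at_k_over_n(self):
        v, f = cumulative_distribution([3.0, 1.0, 2.0])
        assert v.tolist() == [1.0, 2.0, 3.0]
        assert f.tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_equal_pairs_have_zero_below_fraction(self):
        assert fraction_direct_below([5.0, 5.0], [5.0, 5.0]) == 0.0

    def test_recovers_generated_below_unity_fraction(self):
        # campaign generated with 65% of sites shielding-dominated
        config = single_region_config((35, 57, 551), (22, 33, 342), seed=9)
        sites = generate_sites(config, 462, p_shielded=0.65)
        direct = np.array([s.d_air_direct for s in sites])
        soil = np.array([s.d_air_soil for s in sites])
        frac = fraction_direct_below(direct, soil)
        assert abs(frac - 0.65) < 3 * np.sqrt(0.65 * 0.35 / len(sites))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cumulative_distribution([])


def _dense_plate_oracle(data_mask, data_values):
    """Dense construction of the clamped thin-plate system, solved directly."""
    n_lat, n_lon = data_mask.shape
    n = n_lat * n_lon

    rows = []
    def idx(i, j):
        return i * n_lon + j

    for i in range(n_lat):  # d2/dlon2
        for j in range(n_lon - 2):
            r = np.zeros(n)
            r[idx(i, j)] = 1; r[idx(i, j + 1)] = -2; r[idx(i, j + 2)] = 1
            rows.append(r)
    for i in range(n_lat - 2):  # d2/dlat2
        for j in range(n_lon):
            r = np.zeros(n)
            r[idx(i, j)] = 1; r[idx(i + 1, j)] = -2; r[idx(i + 2, j)] = 1
            rows.append(r)
    for i in range(n_lat - 1):  # sqrt(2) * cross term
        for j in range(n_lon - 1):
            r = np.zeros(n)
            s = np.sqrt(2.0)
            r[idx(i, j)] = s; r[idx(i + 1, j + 1)] = s
            r[idx(i, j + 1)] = -s; r[idx(i + 1, j)] = -s
            rows.append(r)
    a = np.array(rows)
    m = a.T @ a
    free = (~data_mask).ravel()
    z0 = np.where(data_mask, data_values, 0.0).ravel()
    sol = np.linalg.solve(m[np.ix_(free, free)], -(m @ z0)[free])
    z = z0.copy()
    z[free] = sol
    return z.reshape(n_lat, n_lon)


class TestGridding:
    def test_single_datum_gives_constant_surface(self):
        pts = pd.DataFrame({"lat": [0.5], "lon": [0.5], "dose_ngy_h": [42.0]})
        grid = grid_minimum_curvature(pts, spacing=0.25, allow_degenerate=True)
        assert np.all(grid.values == 42.0)

    def test_plane_reproduced_exactly(self, rng):
        lat = rng.integers(0, 11, 25) * 0.1
        lon = rng.integers(0, 11, 25) * 0.1
        pts = pd.DataFrame({"lat": lat, "lon": lon})
        pts["dose_ngy_h"] = 3.0 + 2.0 * pts.lat - 1.5 * pts.lon
        grid = grid_minimum_curvature(pts, spacing=0.1)
        expected = 3.0 + 2.0 * grid.lats[:, None] - 1.5 * grid.lons[None, :]
        assert np.abs(grid.values - expected).max() < 1e-8

    def test_matches_dense_oracle_on_small_grid(self, rng):
        # 8x8 grid, 5 data points
        iy = np.array([1, 2, 5, 6, 3])
        ix = np.array([1, 6, 2, 5, 3])
        vals = rng.uniform(10, 100, size=5)
        pts = pd.DataFrame(
            {"lat": iy * 1.0, "lon": ix * 1.0, "dose_ngy_h": vals}
        )
        grid = grid_minimum_curvature(pts, spacing=1.0, mask_radius_cells=10)
        # the gridded surface spans the data bounding box
        oy, ox = iy - iy.min(), ix - ix.min()
        n_lat = int(oy.max()) + 1
        n_lon = int(ox.max()) + 1
        data_mask = np.zeros((n_lat, n_lon), dtype=bool)
        data_values = np.zeros((n_lat, n_lon))
        data_mask[oy, ox] = True
        data_values[oy, ox] = vals
        oracle = _dense_plate_oracle(data_mask, data_values)
        assert np.abs(grid.values - oracle).max() < 1e-6

    def test_iterative_solver_matches_direct(self, rng):
        pts = pd.DataFrame(
            {
                "lat": rng.uniform(0, 1, 15),
                "lon": rng.uniform(0, 1, 15),
                "dose_ngy_h": rng.uniform(20, 120, 15),
            }
        )
        direct = grid_minimum_curvature(pts, spacing=0.1, method="direct")
        iterative = grid_minimum_curvature(
            pts, spacing=0.1, method="cg", tolerance=1e-12
        )
        assert np.abs(direct.values - iterative.values).max() < 1e-6

    def test_translation_equivariance(self, rng):
        pts = pd.DataFrame(
            {
                "lat": rng.uniform(0, 1, 12),
                "lon": rng.uniform(0, 1, 12),
                "dose_ngy_h": rng.uniform(20, 120, 12),
            }
        )
        base = grid_minimum_curvature(pts, spacing=0.1)
        shifted = pts.copy()
        shifted["dose_ngy_h"] += 33.0
        out = grid_minimum_curvature(shifted, spacing=0.1)
        assert np.abs(out.values - base.values - 33.0).max() < 1e-8

    def test_mask_marks_cells_far_from_data(self):
        pts = pd.DataFrame(
            {"lat": [0.0, 0.0, 2.0], "lon": [0.0, 2.0, 0.0], "dose_ngy_h": [1.0, 2.0, 3.0]}
        )
        grid = grid_minimum_curvature(pts, spacing=0.1, mask_radius_cells=3)
        assert grid.mask.any()
        assert not grid.mask[0, 0]

    def test_too_few_points_rejected(self):
        pts = pd.DataFrame({"lat": [0.0, 1.0], "lon": [0.0, 1.0], "dose_ngy_h": [1.0, 2.0]})
        with pytest.raises(ValueError):
            grid_minimum_curvature(pts)
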