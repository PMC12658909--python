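"""Seascape graph construction and least-cost distances: formula-level
checks, an exhaustive path-enumeration oracle, anisotropy and
categorisation rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from seascapegen.connectivity import (CurrentRaster, build_transition_graph,
                                      haversine_km, least_cost_distances,
                                      merge_current_rasters, read_esri_ascii,
                                      sink_source_network, snap_sites_to_grid,
                                      symmetrize_and_categorize, write_esri_ascii)
from seascapegen.genotypes import SiteTable
from seascapegen.simulate import RasterSpec, simulate_current_field


def flat_raster(nr=4, nc=4, u=0.0, v=0.0, cellsize=0.1, lat0=0.0):
    """All-water raster with constant currents, centred near the equator
    so that east/west steps are comparable across rows."""
    return CurrentRaster(np.full((nr, nc), float(u)), np.full((nr, nc), float(v)),
                         xll=0.0, yll=lat0, cellsize=cellsize)


def brute_force_least_cost(graph, src: int, dst: int) -> float:
    """Exhaustive enumeration over all simple paths (oracle for small grids)."""
    costs = graph.costs.toarray()
    n = costs.shape[0]
    best = [np.inf]

    def walk(node, visited, acc):
        if acc >= best[0]:
            return
        if node == dst:
            best[0] = acc
            return
        for nxt in range(n):
            if costs[node, nxt] > 0 and nxt not in visited:
                walk(nxt, visited | {nxt}, acc + costs[node, nxt])

    walk(src, {src}, 0.0)
    return best[0]


class TestAsciiIO:
    def test_round_trip(self, tmp_path):
        grid = np.array([[1.0, np.nan], [0.5, -0.25]])
        path = tmp_path / "g.asc"
        write_esri_ascii(path, grid, ncols=2, nrows=2, xllcorner=-10.0,
                         yllcorner=51.0, cellsize=0.1)
        back, hdr = read_esri_ascii(path)
        assert np.array_equal(back, grid, equal_nan=True)
        assert hdr["cellsize"] == 0.1

    def test_uv_header_mismatch_rejected(self, tmp_path):
        g = np.ones((2, 2))
        write_esri_ascii(tmp_path / "u.asc", g, ncols=2, nrows=2, xllcorner=0,
                         yllcorner=0, cellsize=0.1)
        write_esri_ascii(tmp_path / "v.asc", g, ncols=2, nrows=2, xllcorner=1,
                         yllcorner=0, cellsize=0.1)
        with pytest.raises(ValueError, match="disagree"):
            CurrentRaster.from_ascii(tmp_path / "u.asc", tmp_path / "v.asc")

    def test_raster_round_trip_through_files(self, tmp_path):
        r = simulate_current_field(RasterSpec(n_cols=5, n_rows=4,
                                              land_mask=np.eye(4, 5, dtype=bool)))
        r.to_ascii(tmp_path / "u.asc", tmp_path / "v.asc")
        back = CurrentRaster.from_ascii(tmp_path / "u.asc", tmp_path / "v.asc")
        assert np.array_equal(back.u, r.u, equal_nan=True)
        assert np.array_equal(back.v, r.v, equal_nan=True)


class TestMerge:
    def _pair(self):
        fine = CurrentRaster(np.full((4, 4), 1.0), np.full((4, 4), 2.0),
                             xll=0.4, yll=0.4, cellsize=0.1)
        coarse = CurrentRaster(np.full((4, 4), 9.0), np.full((4, 4), 9.0),
                               xll=0.0, yll=0.0, cellsize=0.2)
        return fine, coarse

    def test_fine_wins_in_overlap(self):
        fine, coarse = self._pair()
        merged = merge_current_rasters(fine, coarse)
        assert merged.cellsize == 0.1
        # overlap region: fine values exactly
        r0 = int(round((merged.yll + merged.n_rows * 0.1 - (fine.yll + 0.4)) / 0.1))
        c0 = int(round((fine.xll - merged.xll) / 0.1))
        assert (merged.u[r0:r0 + 4, c0:c0 + 4] == 1.0).all()

    def test_coarse_only_region_replicated(self):
        fine, coarse = self._pair()
        merged = merge_current_rasters(fine, coarse)
        # bottom-left corner cell comes from the coarse raster
        assert merged.u[-1, 0] == 9.0

    def test_non_integer_ratio_rejected(self):
        fine = flat_raster()
        coarse = CurrentRaster(np.ones((2, 2)), np.ones((2, 2)), 0, 0, 0.15)
        with pytest.raises(ValueError, match="integer multiple"):
            merge_current_rasters(fine, coarse)

    def test_disjoint_extents_union_with_missing(self):
        a = CurrentRaster(np.ones((2, 2)), np.ones((2, 2)), 0.0, 0.0, 0.1)
        b = CurrentRaster(np.full((2, 2), 3.0), np.full((2, 2), 3.0),
                          1.0, 1.0, 0.1)
        merged = merge_current_rasters(a, b)
        assert np.isnan(merged.u).any()
        assert (merged.u[-2:, :2] == 1.0).all()     # a at the south-west
        assert (merged.u[:2, -2:] == 3.0).all()     # b at the north-east


class TestSnap:
    def test_site_at_cell_centre(self):
        r = flat_raster(3, 3, cellsize=1.0, lat0=50.0)
        lat, lon = r.cell_center(1, 1)
        sites = SiteTable(pd.DataFrame(
            {"site_code": ["S"], "latitude": [float(lat)], "longitude": [float(lon)]}))
        snapped = snap_sites_to_grid(sites, r)
        assert snapped["snap_km"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert (snapped["row"].iloc[0], snapped["col"].iloc[0]) == (1, 1)

    def test_land_site_snaps_to_nearest_water_with_tie_flag(self):
        # only the cells due north and due south of the site are water:
        # exactly equidistant, so the (row, col)-first cell wins and is flagged
        u = np.full((3, 3), np.nan)
        u[0, 1] = u[2, 1] = 0.1
        r = CurrentRaster(u, np.zeros((3, 3)), 0.0, 0.0, 1.0)
        lat, lon = r.cell_center(1, 1)
        sites = SiteTable(pd.DataFrame(
            {"site_code": ["S"], "latitude": [float(lat)], "longitude": [float(lon)]}))
        snapped = snap_sites_to_grid(sites, r, max_radius_km=500.0)
        assert snapped["tie"].iloc[0]
        assert (snapped["row"].iloc[0], snapped["col"].iloc[0]) == (0, 1)

    def test_out_of_radius_names_site(self):
        r = flat_raster(2, 2, cellsize=0.1, lat0=0.0)
        sites = SiteTable(pd.DataFrame(
            {"site_code": ["FAR"], "latitude": [60.0], "longitude": [100.0]}))
        with pytest.raises(ValueError, match="FAR"):
            snap_sites_to_grid(sites, r, max_radius_km=50.0)


class TestTransitionGraph:
    def test_zero_current_is_isotropic_and_symmetric(self):
        r = flat_raster(4, 4)
        graph = build_transition_graph(r)
        c = graph.costs.toarray()
        assert np.allclose(c, c.T, atol=1e-12)

    def test_uniform_eastward_edge_costs_match_formula(self):
        s0 = 0.1
        r = flat_raster(2, 3, u=s0, v=0.0, cellsize=1.0, lat0=0.0)
        graph = build_transition_graph(r, s0=s0)
        eps = graph.params["epsilon"]
        i = graph.node_of_cell[(0, 0)]
        j = graph.node_of_cell[(0, 1)]
        lat0, lon0 = r.cell_center(0, 0)
        lat1, lon1 = r.cell_center(0, 1)
        dist = float(haversine_km(lat0, lon0, lat1, lon1))
        c = graph.costs.toarray()
        assert c[i, j] == pytest.approx(dist / (2 * s0), rel=1e-9)   # downstream
        assert c[j, i] == pytest.approx(dist / eps, rel=1e-9)        # upstream
        assert c[i, j] < 0.01 * c[j, i]

    def test_diagonal_steps_use_great_circle_length(self):
        r = flat_raster(3, 3, cellsize=1.0, lat0=0.0)
        graph = build_transition_graph(r)
        c = graph.costs.toarray()
        rook = c[graph.node_of_cell[(1, 1)], graph.node_of_cell[(1, 2)]]
        diag = c[graph.node_of_cell[(1, 1)], graph.node_of_cell[(0, 2)]]
        lat1, lon1 = r.cell_center(1, 1)
        lat2, lon2 = r.cell_center(0, 2)
        expected = float(haversine_km(lat1, lon1, lat2, lon2))
        assert diag > rook
        assert diag * graph.params["s0"] == pytest.approx(expected, rel=1e-9)

    def test_parameter_validation(self):
        r = flat_raster()
        with pytest.raises(ValueError):
            build_transition_graph(r, s0=-1.0)
        with pytest.raises(ValueError):
            build_transition_graph(r, s0=1.0, epsilon=0.0)


class TestLeastCost:
    def _sites(self, raster, cells):
        lat, lon = zip(*(map(float, raster.cell_center(r, c)) for r, c in cells))
        sites = SiteTable(pd.DataFrame({
            "site_code": [f"S{i}" for i in range(len(cells))],
            "latitude": lat, "longitude": lon}))
        return snap_sites_to_grid(sites, raster)

    def test_self_distance_zero(self):
        r = flat_raster(3, 3)
        graph = build_transition_graph(r)
        d = least_cost_distances(graph, self._sites(r, [(0, 0), (2, 2)]))
        assert d.loc["S0", "S0"] == 0.0

    def test_matches_exhaustive_enumeration_on_small_grids(self):
        rng = np.random.default_rng(12)
        for trial in range(3):
            nr, nc = rng.integers(3, 6), rng.integers(3, 6)
            u = rng.uniform(-0.3, 0.3, size=(nr, nc))
            v = rng.uniform(-0.3, 0.3, size=(nr, nc))
            r = CurrentRaster(u, v, 0.0, 0.0, 0.5)
            graph = build_transition_graph(r)
            cells = [(0, 0), (nr - 1, nc - 1)]
            d = least_cost_distances(graph, self._sites(r, cells))
            src = graph.node_of_cell[cells[0]]
            dst = graph.node_of_cell[cells[1]]
            oracle = brute_force_least_cost(graph, src, dst)
            assert d.loc["S0", "S1"] == pytest.approx(oracle, rel=1e-12)

    def test_land_wall_gives_infinite_both_ways(self):
        u = np.full((4, 4), 0.1)
        u[:, 2] = np.nan
        r = CurrentRaster(u, np.zeros((4, 4)), 0.0, 0.0, 0.5)
        graph = build_transition_graph(r)
        d = least_cost_distances(graph, self._sites(r, [(0, 0), (0, 3)]))
        assert np.isinf(d.loc["S0", "S1"]) and np.isinf(d.loc["S1", "S0"])

    def test_uniform_current_strict_anisotropy(self):
        r = flat_raster(4, 5, u=0.2, v=0.0, cellsize=0.2)
        graph = build_transition_graph(r, s0=0.2)
        snapped = self._sites(r, [(1, 0), (1, 4), (3, 2)])
        d = least_cost_distances(graph, snapped)
        for a, b in itertools.combinations(d.index, 2):
            assert d.loc[a, b] != pytest.approx(d.loc[b, a], rel=1e-6)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(13)
        r = CurrentRaster(rng.uniform(-0.2, 0.2, (5, 5)),
                          rng.uniform(-0.2, 0.2, (5, 5)), 0.0, 0.0, 0.3)
        graph = build_transition_graph(r)
        snapped = self._sites(r, [(0, 0), (2, 2), (4, 4)])
        d = least_cost_distances(graph, snapped)
        for a, b, c in itertools.permutations(d.index, 3):
            assert d.loc[a, c] <= d.loc[a, b] + d.loc[b, c] + 1e-9

    def test_refinement_stability_under_uniform_field(self):
        # halving the cell size leaves the cost per unit distance unchanged
        # to < 1% (geo-correction scales per-step costs correctly)
        per_km = {}
        for cs, n in ((0.2, 6), (0.1, 12)):
            r = flat_raster(n, n, u=0.05, v=0.0, cellsize=cs)
            graph = build_transition_graph(r, s0=0.1)
            cells = [(n - 1, 0), (n - 1, n - 1)]
            snapped = self._sites(r, cells)
            d = least_cost_distances(graph, snapped)
            (la0, lo0), (la1, lo1) = (r.cell_center(*c) for c in cells)
            dist = float(haversine_km(la0, lo0, la1, lo1))
            per_km[cs] = d.loc["S0", "S1"] / dist
        assert abs(per_km[0.1] - per_km[0.2]) / per_km[0.2] < 0.01


class TestCategorisation:
    def _directed(self, ab, ba):
        return pd.DataFrame([[0.0, ab], [ba, 0.0]], index=["a", "b"],
                            columns=["a", "b"])

    def test_cat0_when_both_infinite(self):
        out = symmetrize_and_categorize(self._directed(np.inf, np.inf))
        assert out["category"].iloc[0] == "cat0"

    def test_minimum_of_directions_defines_pair_value(self):
        out = symmetrize_and_categorize(self._directed(5e6, 9e5))
        assert out["value"].iloc[0] == 9e5
        assert out["category"].iloc[0] == "cat2"

    def test_middle_band_goes_to_cat1_with_flag(self):
        out = symmetrize_and_categorize(self._directed(2e6, 2.5e6))
        assert out["category"].iloc[0] == "cat1"
        assert bool(out["middle_band"].iloc[0])

    def test_above_cat1_threshold_not_flagged(self):
        out = symmetrize_and_categorize(self._directed(5e6, 4e6))
        assert out["category"].iloc[0] == "cat1"
        assert not bool(out["middle_band"].iloc[0])


class TestSinkSourceNetwork:
    def test_empty_without_cat2(self):
        sym = symmetrize_and_categorize(pd.DataFrame(
            [[0.0, np.inf], [np.inf, 0.0]], index=["a", "b"], columns=["a", "b"]))
        assert len(sink_source_network(sym)) == 0

    def test_weights_inverse_and_direction_from_cheaper_cost(self):
        directed = pd.DataFrame(
            [[0.0, 1e5, 2e5], [9e4, 0.0, np.inf], [3e5, np.inf, 0.0]],
            index=list("abc"), columns=list("abc"))
        sym = symmetrize_and_categorize(directed)
        net = sink_source_network(sym)
        ab = net.loc[(net["source"] == "b") & (net["sink"] == "a")]
        assert len(ab) == 1  # b->a is the cheaper direction (9e4 < 1e5)
        assert ab["weight"].iloc[0] == pytest.approx(1 / 9e4)
        # weights decrease as cost increases
        net_sorted = net.sort_values("weight", ascending=False)
        values = 1.0 / net_sorted["weight"].to_numpy()
        assert (np.diff(values) >= -1e-12).all()
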