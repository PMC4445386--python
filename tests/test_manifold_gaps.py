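import numpy as np
import pytest
from scipy.spatial import cKDTree

from somalayer.core_io import PointCloud
from somalayer.manifold_gaps import (
    Chart,
    ChartDisconnectedError,
    GapParams,
    chart_gap_analysis,
    delaunay_triangulate,
    fit_lognormal,
    grow_convex_region,
    isomap_embed,
    lwr_distance,
    prune_boundary_triangles,
    slice_cloud,
)
from somalayer.synthetic import LayerSpec, generate_folded_layer, _hex_lattice
from oracles import (
    circumcircle_violations,
    largest_empty_convex_polygon_area,
    reference_prune,
)


def _planar_chart(extent=(160.0, 160.0), pitch=10.0, jitter=1.0, seed=0, gaps=()):
    layer = generate_folded_layer(
        LayerSpec(
            extent_um=extent,
            fold_amplitude_um=0.0,
            cell_spacing_um=pitch,
            jitter_um=jitter,
            gaps=list(gaps),
            seed=seed,
        )
    )
    xyz = layer.cloud.xyz
    return Chart(
        member_ids=layer.cloud.ids, coords3d=xyz, coords2d=xyz[:, :2].copy()
    ), layer


class TestSliceCloud:
    def test_reference_interval_arithmetic(self):
        """Extent 3880 at height 2000 / overlap 120 gives exactly the two
        slabs [0, 2000) and [1880, 3880]."""
        z = np.concatenate([[0.0, 3880.0], np.linspace(1, 3879, 50)])
        xyz = np.column_stack([np.zeros_like(z), z, np.zeros_like(z)])
        charts = slice_cloud(PointCloud(xyz), "y", height=2000, overlap=120)
        assert len(charts) == 2
        lo0, hi0 = charts[0].coords3d[:, 1].min(), charts[0].coords3d[:, 1].max()
        lo1, hi1 = charts[1].coords3d[:, 1].min(), charts[1].coords3d[:, 1].max()
        assert lo0 == 0.0 and hi0 < 2000.0
        assert lo1 >= 1880.0 and hi1 == 3880.0

    def test_small_extent_single_chart(self, rng):
        cloud = PointCloud(rng.uniform(0, 100, (40, 3)))
        charts = slice_cloud(cloud, "z", height=2000, overlap=120)
        assert len(charts) == 1
        assert len(charts[0]) == 40

    def test_coverage_and_overlap_multiplicity(self, rng):
        xyz = rng.uniform(0, 5000, (400, 3))
        cloud = PointCloud(xyz)
        charts = slice_cloud(cloud, "x", height=2000, overlap=120)
        counts = np.zeros(400, dtype=int)
        for ch in charts:
            counts[np.searchsorted(cloud.ids, ch.member_ids)] += 1
        assert np.all(counts >= 1)
        assert np.all(counts <= 2)
        # interval membership oracle: recompute per point from the cut grid
        lo = xyz[:, 0].min()
        step = 2000 - 120
        for i, x in enumerate(xyz[:, 0]):
            expected = sum(
                1
                for s in range(len(charts))
                if lo + s * step <= x < lo + s * step + 2000
                or (s == len(charts) - 1 and x == lo + s * step + 2000)
            )
            assert counts[i] == expected

    def test_empty_cloud(self):
        assert slice_cloud(PointCloud(np.empty((0, 3))), "y", 2000, 120) == []

    def test_overlap_must_be_smaller_than_height(self, rng):
        with pytest.raises(ValueError):
            slice_cloud(PointCloud(rng.uniform(0, 1, (5, 3))), "y", 100, 100)


class TestIsomapEmbed:
    def test_flat_sheet_distances_preserved(self, rng):
        chart, layer = _planar_chart(seed=1)
        coplanar = chart.coords3d.copy()
        coplanar[:, 2] = 0.0  # exactly in the plane z = 0
        flat = Chart(member_ids=chart.member_ids, coords3d=coplanar)
        emb = isomap_embed(flat, GapParams())
        n = len(emb)
        i, j = np.triu_indices(n, 1)
        sel = rng.choice(len(i), 5000, replace=False)
        i, j = i[sel], j[sel]
        d3 = np.linalg.norm(coplanar[i] - coplanar[j], axis=1)
        d2 = np.linalg.norm(emb.coords2d[i] - emb.coords2d[j], axis=1)
        assert np.median(np.abs(d2 - d3) / d3) <= 1e-3

    def test_half_cylinder_geodesics_preserved(self, rng):
        R = 50.0
        uv = _hex_lattice((np.pi * R, 300.0), 6.0)
        uv = uv + rng.normal(0, 0.6, uv.shape)
        theta = uv[:, 0] / R
        pts = np.column_stack([R * np.cos(theta), uv[:, 1], R * np.sin(theta)])
        emb = isomap_embed(Chart(member_ids=np.arange(len(uv)), coords3d=pts), GapParams())
        i, j = np.triu_indices(len(uv), 1)
        sel = rng.choice(len(i), 20000, replace=False)
        i, j = i[sel], j[sel]
        geo = np.linalg.norm(uv[i] - uv[j], axis=1)  # analytic cylinder geodesics
        d2 = np.linalg.norm(emb.coords2d[i] - emb.coords2d[j], axis=1)
        assert np.median(np.abs(d2 - geo) / geo) <= 0.02

    def test_two_point_chart_rejected(self):
        with pytest.raises(ValueError):
            isomap_embed(
                Chart(member_ids=[0, 1], coords3d=[[0, 0, 0], [1, 0, 0]]), GapParams()
            )

    def test_disconnected_chart_reports_largest_component(self, rng):
        a = rng.uniform(0, 20, (30, 3))
        b = rng.uniform(2000, 2020, (50, 3))
        chart = Chart(member_ids=np.arange(80), coords3d=np.vstack([a, b]))
        with pytest.raises(ChartDisconnectedError) as exc:
            isomap_embed(chart, GapParams())
        assert len(exc.value.largest_component) == 50

    def test_embedding_deterministic(self):
        chart, _ = _planar_chart(seed=2)
        flat = Chart(member_ids=chart.member_ids, coords3d=chart.coords3d)
        e1 = isomap_embed(flat, GapParams())
        e2 = isomap_embed(flat, GapParams())
        np.testing.assert_allclose(e1.coords2d, e2.coords2d, atol=1e-9)


class TestLwrDistance:
    def test_coplanar_query_zero(self, rng):
        pts = np.column_stack(
            [rng.uniform(0, 50, 50), rng.uniform(0, 50, 50), np.zeros(50)]
        )
        assert lwr_distance(np.array([25.0, 25.0, 0.0]), pts) <= 1e-6

    def test_plane_offset_exact(self, rng):
        pts = np.column_stack(
            [rng.uniform(0, 50, 50), rng.uniform(0, 50, 50), np.zeros(50)]
        )
        d = lwr_distance(np.array([25.0, 25.0, 25.0]), pts)
        assert abs(d - 25.0) <= 1e-6

    def test_sphere_cap_approximated(self, rng):
        """Neighbours on a 20 µm cap of a 100 µm sphere: the quadric follows
        the cap, so a query on the sphere is within 1 µm of it."""
        R = 100.0
        phi = rng.uniform(0, 0.2, 60)  # polar angle, 20 µm cap
        ang = rng.uniform(0, 2 * np.pi, 60)
        pts = np.column_stack(
            [R * np.sin(phi) * np.cos(ang), R * np.sin(phi) * np.sin(ang), R * np.cos(phi)]
        )
        query = np.array([0.0, 0.0, R])  # exactly on the sphere (pole)
        assert lwr_distance(query, pts) <= 1.0

    def test_collinear_neighbourhood_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="degenerate"):
            lwr_distance(np.array([5.0, 1.0, 0.0]), pts)

    def test_too_few_neighbours_rejected(self):
        with pytest.raises(ValueError):
            lwr_distance(np.zeros(3), np.zeros((5, 3)))


class TestDelaunay:
    def test_unit_square(self):
        chart = Chart(
            member_ids=np.arange(4),
            coords3d=np.zeros((4, 3)),
            coords2d=np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float),
        )
        tri = delaunay_triangulate(chart)
        assert tri.n_triangles == 2
        assert tri.triangle_areas().sum() == pytest.approx(1.0)
        assert all(tri.boundary_flags)

    def test_empty_circumcircles(self, rng):
        pts = rng.uniform(0, 100, (150, 2))
        chart = Chart(member_ids=np.arange(150), coords3d=np.zeros((150, 3)), coords2d=pts)
        tri = delaunay_triangulate(chart)
        assert circumcircle_violations(tri.vertices, tri.triangles) == 0

    def test_three_points_single_boundary_triangle(self):
        chart = Chart(
            member_ids=[0, 1, 2],
            coords3d=np.zeros((3, 3)),
            coords2d=np.array([[0, 0], [2, 0], [1, 2]], float),
        )
        tri = delaunay_triangulate(chart)
        assert tri.n_triangles == 1
        assert tri.boundary_flags[0]

    def test_collinear_rejected(self):
        chart = Chart(
            member_ids=np.arange(5),
            coords3d=np.zeros((5, 3)),
            coords2d=np.column_stack([np.arange(5.0), np.arange(5.0)]),
        )
        with pytest.raises(ValueError):
            delaunay_triangulate(chart)

    def test_triangles_ccw_and_adjacency_symmetric(self, rng):
        pts = rng.uniform(0, 50, (80, 2))
        chart = Chart(member_ids=np.arange(80), coords3d=np.zeros((80, 3)), coords2d=pts)
        tri = delaunay_triangulate(chart)
        a = tri.vertices[tri.triangles[:, 0]]
        b = tri.vertices[tri.triangles[:, 1]]
        c = tri.vertices[tri.triangles[:, 2]]
        assert np.all((b - a)[:, 0] * (c - a)[:, 1] - (b - a)[:, 1] * (c - a)[:, 0] > 0)
        for ti, nbrs in enumerate(tri.adjacency):
            for nb in nbrs:
                assert ti in tri.adjacency[nb]


class TestPruneBoundary:
    def test_far_outlier_slivers_removed(self):
        pts = np.vstack(
            [np.random.default_rng(0).uniform(0, 20, (30, 2)), [[500.0, 10.0]]]
        )
        chart = Chart(member_ids=np.arange(31), coords3d=np.zeros((31, 3)), coords2d=pts)
        tri = delaunay_triangulate(chart)
        pruned = prune_boundary_triangles(tri, threshold=100.0)
        assert 30 not in set(pruned.triangles.ravel())  # outlier unreferenced
        assert pruned.n_triangles < tri.n_triangles

    def test_infinite_threshold_identity(self, rng):
        pts = rng.uniform(0, 30, (40, 2))
        chart = Chart(member_ids=np.arange(40), coords3d=np.zeros((40, 3)), coords2d=pts)
        tri = delaunay_triangulate(chart)
        pruned = prune_boundary_triangles(tri, threshold=np.inf)
        assert pruned.n_triangles == tri.n_triangles

    def test_matches_reference_reimplementation(self, rng):
        for trial in range(5):
            pts = rng.uniform(0, 60, (60, 2))
            chart = Chart(member_ids=np.arange(60), coords3d=np.zeros((60, 3)), coords2d=pts)
            tri = delaunay_triangulate(chart)
            thr = 2.5 * float(np.median(tri.edge_lengths()))
            pruned = prune_boundary_triangles(tri, thr)
            ours = {tuple(sorted(t)) for t in pruned.triangles}
            theirs = reference_prune(tri.vertices, tri.triangles, thr)
            assert ours == theirs

    def test_idempotent(self, rng):
        pts = rng.uniform(0, 60, (80, 2))
        chart = Chart(member_ids=np.arange(80), coords3d=np.zeros((80, 3)), coords2d=pts)
        tri = delaunay_triangulate(chart)
        thr = 3.0 * float(np.median(tri.edge_lengths()))
        once = prune_boundary_triangles(tri, thr)
        twice = prune_boundary_triangles(once, thr)
        assert {tuple(sorted(t)) for t in once.triangles} == {
            tuple(sorted(t)) for t in twice.triangles
        }

    def test_threshold_too_small_errors(self, rng):
        pts = rng.uniform(0, 10, (10, 2))
        chart = Chart(member_ids=np.arange(10), coords3d=np.zeros((10, 3)), coords2d=pts)
        tri = delaunay_triangulate(chart)
        with pytest.raises(ValueError, match="threshold"):
            prune_boundary_triangles(tri, 1e-6)


def _region_invariants(tri, region, tol_deg=1.0):
    """Post-hoc check: convexity, vertex emptiness, area additivity."""
    pts = tri.vertices[region.boundary_polygon]
    # convex within tolerance
    v = np.roll(pts, -1, axis=0) - pts
    cross = v[:, 0] * np.roll(v[:, 1], -1) - v[:, 1] * np.roll(v[:, 0], -1)
    dot = v[:, 0] * np.roll(v[:, 0], -1) + v[:, 1] * np.roll(v[:, 1], -1)
    turns = np.arctan2(cross, dot)
    if np.sum(turns) < 0:
        turns = -turns
    assert np.all(turns >= -np.deg2rad(tol_deg) - 1e-12)
    # all member-triangle vertices lie on the boundary polygon, so no
    # triangulation vertex sits strictly inside the region
    member_vertices = set(tri.triangles[sorted(region.triangle_ids)].ravel().tolist())
    assert member_vertices == set(region.boundary_polygon.tolist())
    # area additivity
    areas = tri.triangle_areas()
    assert region.area_um2 == pytest.approx(
        float(areas[sorted(region.triangle_ids)].sum())
    )


class TestGrowConvexRegion:
    def test_single_triangle_region(self):
        chart = Chart(
            member_ids=[0, 1, 2],
            coords3d=np.zeros((3, 3)),
            coords2d=np.array([[0, 0], [2, 0], [1, 2]], float),
        )
        tri = delaunay_triangulate(chart)
        region = grow_convex_region(tri, 0)
        assert region.triangle_ids == frozenset({0})
        assert region.area_um2 == pytest.approx(2.0)

    def test_unit_square_grows_to_both_triangles(self):
        chart = Chart(
            member_ids=np.arange(4),
            coords3d=np.zeros((4, 3)),
            coords2d=np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float),
        )
        tri = delaunay_triangulate(chart)
        for seed in range(2):
            region = grow_convex_region(tri, seed)
            assert region.triangle_ids == frozenset({0, 1})
            assert region.area_um2 == pytest.approx(1.0)

    def test_deterministic(self, rng):
        pts = rng.uniform(0, 60, (50, 2))
        chart = Chart(member_ids=np.arange(50), coords3d=np.zeros((50, 3)), coords2d=pts)
        tri = delaunay_triangulate(chart)
        for seed in range(0, tri.n_triangles, 7):
            r1 = grow_convex_region(tri, seed)
            r2 = grow_convex_region(tri, seed)
            assert r1.triangle_ids == r2.triangle_ids

    def test_regions_satisfy_invariants(self, rng):
        pts = rng.uniform(0, 80, (60, 2))
        chart = Chart(member_ids=np.arange(60), coords3d=np.zeros((60, 3)), coords2d=pts)
        tri = delaunay_triangulate(chart)
        for seed in range(tri.n_triangles):
            _region_invariants(tri, grow_convex_region(tri, seed))

    def test_disc_gap_bounded_by_exhaustive_optimum(self, rng):
        """Max grown area recovers >= 75% of a removed disc and never
        exceeds the exhaustive largest-empty-convex-polygon area."""
        rho = 20.0
        for trial in range(3):
            g = np.arange(0, 80, 11.0)
            xx, yy = np.meshgrid(g, g)
            pts = np.column_stack([xx.ravel(), yy.ravel()])
            pts = pts + rng.normal(0, 1.2, pts.shape)
            pts = pts[(pts[:, 0] - 40) ** 2 + (pts[:, 1] - 40) ** 2 > rho**2]
            assert len(pts) <= 60
            chart = Chart(
                member_ids=np.arange(len(pts)),
                coords3d=np.column_stack([pts, np.zeros(len(pts))]),
                coords2d=pts,
            )
            tri = delaunay_triangulate(chart)
            grown = max(
                grow_convex_region(tri, s).area_um2 for s in range(tri.n_triangles)
            )
            oracle = largest_empty_convex_polygon_area(pts)
            assert grown <= oracle + 1e-6
            assert grown >= 0.75 * np.pi * rho**2


class TestChartGapAnalysis:
    def test_uniform_grid_no_outlier_gap(self):
        chart, _ = _planar_chart(pitch=10.0, jitter=1.0, seed=3)
        res = chart_gap_analysis(chart, GapParams())
        cells = np.array(list(res.cell_areas.values()))
        assert np.max(cells) <= 3.0 * np.median(cells)

    def test_planted_disc_recovered_by_bordering_cells(self):
        gap = (80.0, 80.0, 30.0)
        chart, layer = _planar_chart(extent=(160, 160), pitch=10.0, seed=4, gaps=[gap])
        res = chart_gap_analysis(chart, GapParams())
        A = np.pi * gap[2] ** 2
        best = max(res.cell_areas.values())
        assert best >= 0.75 * A
        # the best cells border the disc
        ids = [pid for pid, a in res.cell_areas.items() if a == best]
        idx = np.searchsorted(chart.member_ids, ids)
        d = np.linalg.norm(chart.coords3d[idx, :2] - [gap[0], gap[1]], axis=1)
        assert np.all(d <= gap[2] + 2 * 10.0)

    def test_three_cell_chart(self):
        chart = Chart(
            member_ids=[0, 1, 2],
            coords3d=np.array([[0, 0, 0], [2, 0, 0], [1, 2, 0]], float),
            coords2d=np.array([[0, 0], [2, 0], [1, 2]], float),
        )
        res = chart_gap_analysis(chart, GapParams())
        for pid in (0, 1, 2):
            assert res.cell_areas[pid] == pytest.approx(2.0)

    def test_mesh_face_count_matches_surviving_triangles(self):
        chart, _ = _planar_chart(seed=5)
        res = chart_gap_analysis(chart, GapParams())
        assert len(res.mesh.faces) == res.triangulation.n_triangles
        assert len(res.mesh.face_scalar) == res.triangulation.n_triangles

    def test_areas_invariant_under_rigid_motion(self):
        chart, _ = _planar_chart(extent=(120, 120), seed=6)
        base = chart_gap_analysis(
            Chart(member_ids=chart.member_ids, coords3d=chart.coords3d), GapParams()
        )
        # rotate + translate the 3D cloud
        ang = 0.7
        Rz = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        ang2 = 0.4
        Rx = np.array(
            [[1, 0, 0], [0, np.cos(ang2), -np.sin(ang2)], [0, np.sin(ang2), np.cos(ang2)]]
        )
        moved = chart.coords3d @ Rz.T @ Rx.T + np.array([50.0, -20.0, 7.0])
        rot = chart_gap_analysis(
            Chart(member_ids=chart.member_ids, coords3d=moved), GapParams()
        )
        a = np.array([base.cell_areas[k] for k in sorted(base.cell_areas)])
        b = np.array([rot.cell_areas[k] for k in sorted(rot.cell_areas)])
        assert np.median(np.abs(a - b) / np.maximum(a, 1e-9)) <= 1e-3


class TestFitLognormal:
    def test_degenerate_equal_sample(self):
        fit = fit_lognormal(np.full(50, np.e**7))
        assert fit.mu == pytest.approx(7.0)
        assert fit.sigma == pytest.approx(0.0, abs=1e-12)
        assert fit.ci99_sigma[0] == 0.0

    def test_parameter_recovery(self):
        mu, sigma, n = 7.779, 0.488, 100_000
        rng = np.random.default_rng(8)
        areas = np.exp(rng.normal(mu, sigma, n))
        fit = fit_lognormal(areas)
        se_mu = sigma / np.sqrt(n)
        se_sigma = sigma / np.sqrt(2 * n)
        assert abs(fit.mu - mu) <= 3 * se_mu
        assert abs(fit.sigma - sigma) <= 3 * se_sigma
        assert fit.ci99_mu[0] <= mu <= fit.ci99_mu[1]
        assert fit.ci99_sigma[0] <= sigma <= fit.ci99_sigma[1]

    def test_mle_equals_grid_search(self):
        rng = np.random.default_rng(9)
        areas = np.exp(rng.normal(7.0, 0.5, 100))
        fit = fit_lognormal(areas)
        logs = np.log(areas)

        def loglik(m, s):
            return -len(logs) * np.log(s) - np.sum((logs - m) ** 2) / (2 * s**2)

        mus = np.linspace(fit.mu - 0.2, fit.mu + 0.2, 4001)
        sigmas = np.linspace(max(fit.sigma - 0.2, 1e-3), fit.sigma + 0.2, 4001)
        best_mu = mus[np.argmax([loglik(m, fit.sigma) for m in mus])]
        best_sigma = sigmas[np.argmax([loglik(fit.mu, s) for s in sigmas])]
        assert abs(best_mu - fit.mu) <= 1e-4
        assert abs(best_sigma - fit.sigma) <= 1e-4

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal(np.array([1.0, -2.0, 3.0]))
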