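"""Geometry, cavity-volume and prolate-coordinate tests."""

import numpy as np
import pytest

from bivent import geometry as G


class TestBuild:
    def test_counts_and_regions_partition(self, default_mesh):
        m = default_mesh
        assert m.n_nodes > 0 and m.n_elements > 0
        regions = set(np.unique(m.element_region))
        assert regions == {G.REGION_LV_FREE_WALL, G.REGION_SEPTUM,
                           G.REGION_RV_FREE_WALL}

    def test_element_volumes_positive(self, default_mesh):
        assert default_mesh.element_volumes().min() > 0

    def test_element_indices_in_range(self, default_mesh):
        m = default_mesh
        assert m.elements.max() < m.n_nodes
        assert m.elements.min() >= 0

    def test_each_boundary_facet_in_exactly_one_surface(self, default_mesh):
        from collections import Counter
        m = default_mesh
        seen = Counter()
        for name, facets in m.surfaces.items():
            for f in facets:
                seen[tuple(sorted(set(f)))] += 1
        dupes = [f for f, c in seen.items() if c > 1]
        assert dupes == []

    def test_deterministic_bitwise(self):
        cfg = G.GeometryConfig(n_circ=8, n_long=3)
        a = G.build_idealized_biventricular(cfg)
        b = G.build_idealized_biventricular(cfg)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.elements, b.elements)

    def test_zero_wall_thickness_rejected(self):
        with pytest.raises(G.GeometryError):
            G.GeometryConfig(lv_wall_thickness=0.0)

    def test_degenerate_rv_rejected(self):
        with pytest.raises(G.GeometryError):
            G.GeometryConfig(rv_span=2 * np.pi)

    def test_single_transmural_element_rejected(self):
        with pytest.raises(G.GeometryError):
            G.GeometryConfig(n_trans=1)


class TestCavityVolume:
    def test_lv_matches_truncated_ellipsoid_closed_form(self, default_mesh):
        v = G.cavity_volume(default_mesh, None, "LV")
        expect = G.analytic_lv_cavity_volume(default_mesh.config)
        assert v == pytest.approx(expect, rel=0.02)
        assert expect == pytest.approx(
            2 / 3 * np.pi * 33.0 ** 2 * 80.0 / 1000.0)

    @pytest.mark.parametrize("base_mu_deg", [75.0, 105.0])
    def test_base_truncation_height_volume(self, base_mu_deg):
        """Moving the base-truncation plane above/below the equator still
        matches the closed-form ellipsoid-segment volume."""
        cfg = G.GeometryConfig(n_circ=8, n_long=3, base_mu_deg=base_mu_deg)
        m = G.build_idealized_biventricular(cfg)
        v = G.cavity_volume(m, None, "LV")
        assert v == pytest.approx(G.analytic_lv_cavity_volume(cfg),
                                  rel=1e-9)
        assert m.element_volumes().min() > 0

    def test_refinement_changes_volume_below_half_percent(self, default_mesh):
        v1 = G.cavity_volume(default_mesh, None, "LV")
        cfg = default_mesh.config
        import dataclasses
        cfg2 = dataclasses.replace(cfg, n_circ=2 * cfg.n_circ,
                                   n_long=2 * cfg.n_long)
        m2 = G.build_idealized_biventricular(cfg2)
        v2 = G.cavity_volume(m2, None, "LV")
        assert abs(v2 - v1) / v1 < 0.005

    def test_rigid_motion_invariance(self, default_mesh, rng):
        m = default_mesh
        v0 = {c: G.cavity_volume(m, None, c) for c in ("LV", "RV")}
        shift = np.tile(rng.normal(size=3) * 10, (m.n_nodes, 1))
        for c in ("LV", "RV"):
            v = G.cavity_volume(m, shift, c)
            assert abs(v - v0[c]) <= 1e-9 * v0[c]

    def test_uniform_shrink_scaling_law(self, default_mesh):
        m = default_mesh
        u = -0.1 * m.nodes  # 10% isotropic shrink about the origin
        for c in ("LV", "RV"):
            v0 = G.cavity_volume(m, None, c)
            v = G.cavity_volume(m, u, c)
            assert v == pytest.approx(v0 * 0.9 ** 3, rel=1e-9)

    def test_unknown_cavity_raises(self, default_mesh):
        with pytest.raises(KeyError):
            G.cavity_volume(default_mesh, None, "LA")


class TestProlate:
    def test_round_trip_random_points(self, rng):
        for _ in range(20):
            p = rng.normal(size=3) * 40
            pc = G.prolate_coordinates(p, focus=25.0)
            assert np.abs(pc.to_cartesian() - p).max() < 1e-9
            assert 0 <= pc.mu <= np.pi
            assert -np.pi <= pc.theta <= np.pi

    def test_axis_point_conventions(self):
        pc = G.prolate_coordinates([0, 0, 60.0], focus=25.0)
        assert pc.theta == 0.0
        assert pc.mu == 0.0

    def test_equatorial_plane(self):
        pc = G.prolate_coordinates([40.0, 0, 0], focus=25.0)
        assert pc.mu == pytest.approx(np.pi / 2)

    def test_frame_alignment(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        p = rng.normal(size=3) * 30
        pc = G.prolate_coordinates(p, focus=20.0, frame=Q)
        assert np.abs(pc.to_cartesian(frame=Q) - p).max() < 1e-9

    def test_invalid_focus(self):
        with pytest.raises(ValueError):
            G.prolate_coordinates([1, 2, 3], focus=-1.0)


class TestFibers:
    def test_orthonormal_triads(self, fast_mesh, fast_fibers):
        fb = fast_fibers
        assert np.abs(np.linalg.norm(fb.f0, axis=-1) - 1).max() < 1e-12
        assert np.abs(np.linalg.norm(fb.s0, axis=-1) - 1).max() < 1e-12
        assert np.abs(np.einsum("egi,egi->eg", fb.f0, fb.s0)).max() < 1e-12
        assert np.abs(fb.n0 - np.cross(fb.f0, fb.s0)).max() < 1e-12

    def test_helix_affine_in_depth(self, fast_mesh, fast_fibers):
        from bivent import elements as el
        N = el.shape(fast_fibers.local_points)
        par = np.einsum("ga,eap->egp", N, fast_mesh.elem_param)
        predicted = -60 + par[..., 2] * 120
        assert np.abs(predicted - fast_fibers.helix_angle).max() < 0.5

    def test_surface_endpoint_angles(self, fast_mesh):
        from bivent.fibers import assign_fiber_sheet
        epi = assign_fiber_sheet(fast_mesh,
                                 local_points=np.array([[0.0, 0.0, -1.0]]))
        endo = assign_fiber_sheet(fast_mesh,
                                  local_points=np.array([[0.0, 0.0, 1.0]]))
        import bivent.geometry as G
        lv = fast_mesh.elem_wall == G.WALL_LV
        # elements touching the epicardial surface have d=0 on their
        # zeta=-1 face, endocardial-layer elements d=1 on zeta=+1
        d_epi = fast_mesh.elem_param[:, 0, 2]   # node-0 depth
        d_endo = fast_mesh.elem_param[:, 7, 2]
        assert np.allclose(epi.helix_angle[d_epi == 0.0], -60.0)
        assert np.allclose(endo.helix_angle[d_endo == 1.0], 60.0)

    def test_midwall_fiber_circumferential(self, fast_mesh):
        from bivent.fibers import assign_fiber_sheet
        # a point at d = 0.5 has zero helix angle: fiber purely
        # circumferential (no longitudinal component)
        fb = assign_fiber_sheet(fast_mesh)
        mid = np.isclose(fb.helix_angle, 0.0, atol=1e-9)
        if np.any(mid):
            f0 = fb.f0[mid]
            assert np.abs(f0 @ np.array([0.0, 0.0, 1.0])).max() < 0.2
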