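"""FE mechanics tests: shear cube vs closed form, pressure inflation,
boundary-condition behavior, and a linear-elastic thick-sphere oracle."""

import dataclasses

import numpy as np
import pytest

import bivent.elements as el
from bivent import fem
from bivent import materials as mat
from bivent.fem import Loads
from bivent.fibers import FiberField
from bivent.geometry import Mesh

P = mat.CHF_REFERENCE


class TestShearCube:
    def test_zero_amount_zero_stress(self):
        _, s = fem.simulate_shear_cube("fs", [0.0], P)
        assert s[0] == 0.0

    def test_anisotropy_fs_vs_sf(self):
        _, s_fs = fem.simulate_shear_cube("fs", [0.3], P)
        _, s_sf = fem.simulate_shear_cube("sf", [0.3], P)
        assert s_fs[0] != pytest.approx(s_sf[0], rel=1e-3)

    @pytest.mark.parametrize("mode", ["fs", "ns"])
    def test_fe_matches_homogeneous_closed_form(self, mode):
        amounts = [0.25, 0.5]
        _, s = fem.simulate_shear_cube(mode, amounts, P)
        for g, fe_s in zip(amounts, s):
            analytic = fem.analytic_shear_stress(mode, g, P)
            assert fe_s == pytest.approx(analytic, rel=0.02)

    def test_free_lateral_faces_soften_response(self):
        _, s_free = fem.simulate_shear_cube("fs", [0.3], P, lateral="free")
        analytic = fem.analytic_shear_stress("fs", 0.3, P)
        assert s_free[0] < analytic  # edge effects relax the cube

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            fem.simulate_shear_cube("fx", [0.1], P)

    def test_all_modes_positive_stress(self):
        for mode in fem.SHEAR_MODES:
            s = fem.analytic_shear_stress(mode, 0.2, P)
            assert s > 0


class TestHeartStatics:
    def test_unloaded_equilibrium_zero_displacement(self, fast_mesh,
                                                    fast_fibers):
        model = fem.make_heart_model(fast_mesh, fast_fibers)
        st = fem.solve_static(model, 0.0, 0.0)
        assert np.abs(st.displacement).max() < 1e-8

    def test_volume_monotone_in_pressure(self, fast_mesh, fast_fibers):
        model = fem.make_heart_model(fast_mesh, fast_fibers)
        st1 = fem.solve_static(model, 2.0, 1.0)
        st2 = fem.solve_static(model, 5.0, 2.5,
                               u0=st1.displacement.ravel(),
                               prev=fem.heart_loads(2.0, 1.0))
        v0 = fast_mesh.element_volumes().sum()  # not cavity; sanity only
        from bivent.geometry import cavity_volume
        ref = cavity_volume(fast_mesh, None, "LV")
        assert st1.volumes["LV"] > ref
        assert st2.volumes["LV"] > st1.volumes["LV"]
        assert st2.volumes["RV"] > st1.volumes["RV"]
        assert v0 > 0

    def test_incompressibility_at_edp_loads(self, fast_mesh, fast_fibers):
        """Near-incompressibility under end-diastolic loading.

        The mean-dilatation (SRI) formulation penalizes the element-mean
        J, which stays within 1e-2 of unity; pointwise J at off-centroid
        quadrature points of coarse linear hexes drifts more (the
        isochoric energy is J-independent) and is bounded loosely here.
        """
        model = fem.make_heart_model(fast_mesh, fast_fibers)
        st = fem.solve_static(model, 12.0, 5.0)
        st = fem.solve_static(model, 23.0, 9.0,
                              u0=st.displacement.ravel(),
                              prev=fem.heart_loads(12.0, 5.0))
        u_elem = st.displacement[fast_mesh.elements]
        Jc = np.linalg.det(model._defgrad(u_elem, model.dNdXc))
        assert np.abs(Jc - 1).max() < 1e-2
        jmin, jmax = st.J_range
        assert max(abs(jmin - 1), abs(jmax - 1)) < 0.05

    def test_annulus_contracts_radially_under_active_tension(
            self, fast_mesh, fast_fibers):
        model = fem.make_heart_model(fast_mesh, fast_fibers)
        st = fem.solve_static(model, 0.0, 0.0, t_active=0.17,
                              active_amp=1.0)
        ring = fast_mesh.annulus_nodes
        x0 = fast_mesh.nodes[ring]
        x1 = x0 + st.displacement[ring]
        c0, c1 = x0.mean(axis=0), x1.mean(axis=0)
        r0 = np.linalg.norm((x0 - c0)[:, :2], axis=1).mean()
        r1 = np.linalg.norm((x1 - c1)[:, :2], axis=1).mean()
        assert r1 < r0                      # radial contraction allowed
        assert np.abs(c1[:2] - c0[:2]).max() < 1e-8  # centroid pinned

    def test_hyperelastic_load_unload_returns_to_baseline(
            self, fast_mesh, fast_fibers):
        model = fem.make_heart_model(fast_mesh, fast_fibers)
        st = fem.solve_static(model, 10.0, 4.0)
        peak = np.abs(st.displacement).max()
        back = fem.solve_static(model, 0.0, 0.0,
                                u0=st.displacement.ravel(),
                                prev=fem.heart_loads(10.0, 4.0))
        assert np.abs(back.displacement).max() < 1e-3 * peak


def _thick_sphere_octant(a, b, n_th=6, n_phi=6, n_r=3):
    """Octant of a thick spherical shell as collapsed-hex mesh with a
    pressurized inner surface; symmetry planes x=0, y=0, z=0."""
    th = np.linspace(0, np.pi / 2, n_th + 1)     # azimuth
    ph = np.linspace(0, np.pi / 2, n_phi + 1)    # polar, 0 = +z pole
    r = np.linspace(a, b, n_r + 1)
    nid = {}
    nodes = []
    for k, rr in enumerate(r):
        for j, pp in enumerate(ph):
            if j == 0:
                nid[(0, 0, k)] = len(nodes)
                nodes.append([0.0, 0.0, rr])
                continue
            for i, tt in enumerate(th):
                nid[(i, j, k)] = len(nodes)
                nodes.append([rr * np.sin(pp) * np.cos(tt),
                              rr * np.sin(pp) * np.sin(tt),
                              rr * np.cos(pp)])
    nodes = np.asarray(nodes)

    def gid(i, j, k):
        return nid[(0, 0, k)] if j == 0 else nid[(i, j, k)]

    elems, inner = [], []
    for k in range(n_r):
        for j in range(n_phi):
            for i in range(n_th):
                conn = [gid(i, j, k), gid(i + 1, j, k),
                        gid(i + 1, j + 1, k), gid(i, j + 1, k),
                        gid(i, j, k + 1), gid(i + 1, j, k + 1),
                        gid(i + 1, j + 1, k + 1), gid(i, j + 1, k + 1)]
                elems.append(conn)
                if k == 0:
                    inner.append([conn[0], conn[3], conn[2], conn[1]])
    elems = np.asarray(elems)
    # ensure positive Jacobians
    pts, _ = el.gauss_points(2)
    _, detJ = el.jacobians(nodes[elems], el.dshape(pts))
    if np.all(detJ < 0):
        elems = elems[:, [4, 5, 6, 7, 0, 1, 2, 3]]
    inner = np.asarray(inner)
    # orient inner facets solid-outward (toward the center)
    pfac = nodes[inner]
    nrm = np.cross(pfac[:, 2] - pfac[:, 0], pfac[:, 3] - pfac[:, 1])
    cent = pfac.mean(axis=1)
    flip = np.einsum("fi,fi->f", nrm, -cent) < 0
    inner[flip] = inner[flip][:, ::-1]
    mesh = Mesh(nodes=nodes, elements=elems,
                element_region=np.zeros(len(elems), dtype=int),
                surfaces={"INNER": inner}, cavity_facets={},
                cavity_caps={}, elem_param=np.zeros((len(elems), 8, 3)),
                elem_wall=np.zeros(len(elems), dtype=int),
                annulus_nodes=np.empty(0, dtype=int),
                base_nodes=np.empty(0, dtype=int), markers={}, config=None)
    return mesh


class TestThickSphereOracle:
    def test_isotropic_pressurized_sphere_matches_lame(self):
        """Small-pressure inflation of an isotropic incompressible-ish
        thick sphere against the closed-form linear-elastic solution
        u(r) = p a^3/(b^3-a^3) (r/(3K) + b^3/(4 mu r^2))."""
        a, b = 20.0, 30.0
        iso = dataclasses.replace(P, a_f=0.0, a_s=0.0, a_fs=0.0)
        mesh = _thick_sphere_octant(a, b)
        ngp = 8
        f0 = np.tile(np.eye(3)[0], (mesh.n_elements, ngp, 1))
        s0 = np.tile(np.eye(3)[1], (mesh.n_elements, ngp, 1))
        fibers = FiberField(f0=f0, s0=s0, n0=np.cross(f0, s0),
                            helix_angle=np.zeros((mesh.n_elements, ngp)),
                            local_points=el.gauss_points(2)[0])
        fixed_dofs, fixed_vals = [], []
        for nd, (x, y, z) in enumerate(mesh.nodes):
            if abs(x) < 1e-9:
                fixed_dofs.append(3 * nd)
                fixed_vals.append(0.0)
            if abs(y) < 1e-9:
                fixed_dofs.append(3 * nd + 1)
                fixed_vals.append(0.0)
            if abs(z) < 1e-9:
                fixed_dofs.append(3 * nd + 2)
                fixed_vals.append(0.0)
        model = fem.FEModel(mesh, fibers, iso,
                            fixed_dofs=np.array(fixed_dofs),
                            fixed_vals=np.array(fixed_vals),
                            pressure_surfaces=("INNER",))
        p_kpa = 0.4
        u = model.solve(Loads(pressures={"INNER": p_kpa}),
                        prev=Loads(pressures={"INNER": 0.0}))
        disp = u.reshape(-1, 3)
        # radial displacement of outer-surface nodes
        router = np.linalg.norm(mesh.nodes, axis=1) > b - 1e-6
        ur_fe = np.einsum("ni,ni->n", disp[router],
                          mesh.nodes[router]
                          / np.linalg.norm(mesh.nodes[router], axis=1,
                                           keepdims=True))
        mu = iso.a            # small-strain shear modulus of exp(...)
        K = 2.0 / iso.D
        ur_lame = p_kpa * a ** 3 / (b ** 3 - a ** 3) \
            * (b / (3 * K) + b ** 3 / (4 * mu * b ** 2))
        assert ur_fe.mean() == pytest.approx(ur_lame, rel=0.05)
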