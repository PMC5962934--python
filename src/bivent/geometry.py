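"""Idealized biventricular geometry.

The solid is built from two intersecting truncated ellipsoidal shells: a
thick-walled LV (truncated at a configurable base plane, by default the
equatorial plane z = 0, apex at negative z) and a thinner crescent-shaped
RV free wall attached to the LV
epicardium over a configurable circumferential span.  The portion of LV
wall covered by the RV cavity is labeled SEPTUM.  This is a synthetic
stand-in for a segmented patient mesh that preserves the topology needed
by the downstream metrics: LV/RV cavities, septum, base plane, annulus
ring, and the anterior/posterior ventricular junction markers.

Every node carries parametric coordinates (theta, mu, d) of its wall
(circumferential angle, polar angle from the base, and normalized
transmural depth with d = 0 on the epicardium and d = 1 on the
endocardium) from which the rule-based fiber architecture is evaluated.

Units: mm for lengths, ml for volumes.

The in-plane node radius carries a resolution-dependent compensation
factor sqrt(dtheta / sin dtheta) so the faceted cavity encloses the same
volume as the smooth ellipsoid it discretizes; the discrete cavity volume
then converges to the analytic target from the coarsest resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import elements as el


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric input."""


class TopologyError(ValueError):
    """Raised when a surface expected to be closed is not."""


REGION_LV_FREE_WALL = 0
REGION_SEPTUM = 1
REGION_RV_FREE_WALL = 2
REGION_NAMES = {REGION_LV_FREE_WALL: "LV_FREE_WALL",
                REGION_SEPTUM: "SEPTUM",
                REGION_RV_FREE_WALL: "RV_FREE_WALL"}
REGION_IDS = {v: k for k, v in REGION_NAMES.items()}

WALL_LV = 0
WALL_RV = 1


@dataclass(frozen=True)
class GeometryConfig:
    """Dimensions (mm) and mesh resolution of the idealized biventricle.

    Defaults give a dilated-heart LV with an unloaded cavity volume of
    about 180 ml and an RV cavity sized to the same order as the LV.
    """

    lv_endo_radius: float = 33.0      # equatorial endocardial radius
    lv_endo_apex: float = 80.0        # endocardial apex depth (|z|)
    lv_wall_thickness: float = 8.0
    base_mu_deg: float = 90.0         # polar angle of the truncation
    #                                   plane (90 = equatorial base)
    rv_theta_start: float = 0.0       # circumferential start of RV patch
    rv_span: float = np.pi            # circumferential extent of RV patch
    rv_mu_frac: float = 0.72          # fraction of base->apex range covered
    rv_bulge: float = 26.0            # max free-wall offset from LV epi
    rv_wall_thickness: float = 5.0
    n_circ: int = 12                  # circumferential elements (LV, full)
    n_long: int = 5                   # longitudinal element rings below base
    n_trans: int = 2                  # transmural elements, LV wall
    n_trans_rv: int = 2               # transmural elements, RV wall

    def __post_init__(self):
        for name in ("lv_endo_radius", "lv_endo_apex", "lv_wall_thickness",
                     "rv_bulge", "rv_wall_thickness", "rv_span"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if not (0.1 <= self.rv_mu_frac <= 0.95):
            raise GeometryError("rv_mu_frac must lie in [0.1, 0.95]")
        if self.rv_span >= 2 * np.pi:
            raise GeometryError("rv_span must be < 2*pi")
        if self.n_circ < 6 or self.n_long < 2:
            raise GeometryError("resolution too coarse (n_circ>=6, n_long>=2)")
        if self.n_trans < 2 or self.n_trans_rv < 2:
            raise GeometryError("need >= 2 elements through each wall")
        if not (60.0 <= self.base_mu_deg <= 120.0):
            raise GeometryError("base_mu_deg must lie in [60, 120]")

    @property
    def mu_base(self):
        return np.deg2rad(self.base_mu_deg)

    # RV patch occupies whole theta cells; snap span to the grid
    @property
    def _i_rv(self):
        dtheta = 2 * np.pi / self.n_circ
        i0 = int(round(self.rv_theta_start / dtheta))
        ncells = max(2, int(round(self.rv_span / dtheta)))
        if ncells >= self.n_circ:
            raise GeometryError("RV span covers the full circumference")
        return i0, i0 + ncells

    @property
    def _j_rv(self):
        j = int(round(self.rv_mu_frac * self.n_long))
        return min(max(j, 1), self.n_long - 1)


@dataclass
class Mesh:
    """Hexahedral biventricular mesh with labeled regions and surfaces."""

    nodes: np.ndarray                 # (N, 3) mm
    elements: np.ndarray              # (E, 8) int
    element_region: np.ndarray        # (E,) int, REGION_* codes
    surfaces: dict                    # name -> (n, 4) facets, solid-outward
    cavity_facets: dict               # 'LV'/'RV' -> (n, 4), out-of-cavity
    cavity_caps: dict                 # 'LV' -> ring ids; 'RV' -> (inner, outer)
    elem_param: np.ndarray            # (E, 8, 3): theta (unwrapped), mu, d
    elem_wall: np.ndarray             # (E,) WALL_LV / WALL_RV
    annulus_nodes: np.ndarray
    base_nodes: np.ndarray
    markers: dict                     # septum_mid, junction_ant, junction_post
    config: GeometryConfig = field(repr=False, default=None)

    @property
    def n_nodes(self):
        return self.nodes.shape[0]

    @property
    def n_elements(self):
        return self.elements.shape[0]

    def element_volumes(self, displacement=None):
        x = self.nodes if displacement is None else self.nodes + displacement
        return el.element_volumes(x[self.elements])


# ---------------------------------------------------------------------------
# parametric wall maps


def _theta_compensation(n_circ):
    dtheta = 2 * np.pi / n_circ
    return np.sqrt(dtheta / np.sin(dtheta))


def _ring_mus(cfg: GeometryConfig):
    """Polar angles of the longitudinal rings, base plane to (near) apex."""
    mu0 = cfg.mu_base
    return mu0 + (np.pi - mu0) * np.arange(cfg.n_long + 1) / (cfg.n_long + 1)


def _mu_compensation(cfg: GeometryConfig):
    """In-plane inflation so the revolved endocardial polyline encloses the
    analytic truncated-ellipsoid volume (longitudinal chord correction)."""
    R, C = cfg.lv_endo_radius, cfg.lv_endo_apex
    mus = np.append(_ring_mus(cfg), np.pi)
    rho = R * np.sin(mus)
    z = C * np.cos(mus)
    # frustum volumes between consecutive rings (pole included, rho -> 0)
    v_poly = np.pi / 3 * np.sum(
        (z[:-1] - z[1:]) * (rho[:-1] ** 2 + rho[:-1] * rho[1:] + rho[1:] ** 2))
    v_exact = analytic_lv_cavity_volume(cfg) * 1000.0
    return np.sqrt(v_exact / v_poly)


def _inplane_factor(cfg: GeometryConfig):
    return _theta_compensation(cfg.n_circ) * _mu_compensation(cfg)


def lv_wall_point(cfg: GeometryConfig, theta, mu, d):
    """LV shell map: d = 0 epicardium, d = 1 endocardium; mu in [pi/2, pi]."""
    alpha = _inplane_factor(cfg)
    t = cfg.lv_wall_thickness
    r = (cfg.lv_endo_radius + (1.0 - np.asarray(d)) * t) * alpha
    c = cfg.lv_endo_apex + (1.0 - np.asarray(d)) * t
    sm, cm = np.sin(mu), np.cos(mu)
    return np.stack([r * sm * np.cos(theta), r * sm * np.sin(theta),
                     c * cm], axis=-1)


def _lv_epi_normal(cfg: GeometryConfig, theta, mu):
    """Outward unit normal of the LV epicardial ellipsoid."""
    alpha = _inplane_factor(cfg)
    Re = (cfg.lv_endo_radius + cfg.lv_wall_thickness) * alpha
    Ce = cfg.lv_endo_apex + cfg.lv_wall_thickness
    p = lv_wall_point(cfg, theta, mu, 0.0)
    n = np.stack([p[..., 0] / Re**2, p[..., 1] / Re**2, p[..., 2] / Ce**2],
                 axis=-1)
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def _rv_bulge(cfg: GeometryConfig, theta, mu):
    i0, i1 = cfg._i_rv
    dtheta = 2 * np.pi / cfg.n_circ
    th0, th1 = i0 * dtheta, i1 * dtheta
    mu0 = cfg.mu_base
    mu1 = mu0 + (np.pi - mu0) * cfg._j_rv / (cfg.n_long + 1)
    tau = np.clip((np.asarray(theta) - th0) / (th1 - th0), 0.0, 1.0)
    nu = np.clip((np.asarray(mu) - mu0) / (mu1 - mu0), 0.0, 1.0)
    return cfg.rv_bulge * np.sin(np.pi * tau) * np.cos(np.pi / 2 * nu)


def rv_wall_point(cfg: GeometryConfig, theta, mu, d):
    """RV free-wall map: d = 0 outer epicardium, d = 1 RV endocardium."""
    offset = _rv_bulge(cfg, theta, mu) + (1.0 - np.asarray(d)) \
        * cfg.rv_wall_thickness
    base = lv_wall_point(cfg, theta, mu, 0.0)
    n = _lv_epi_normal(cfg, theta, mu)
    return base + offset[..., None] * n


def wall_point(cfg: GeometryConfig, wall, theta, mu, d):
    if wall == WALL_LV:
        return lv_wall_point(cfg, theta, mu, d)
    return rv_wall_point(cfg, theta, mu, d)


# ---------------------------------------------------------------------------
# prolate spheroidal coordinates


@dataclass(frozen=True)
class ProlateCoords:
    lam: float
    mu: float
    theta: float
    focus: float

    def to_cartesian(self, frame=None):
        f = self.focus
        rho = f * np.sinh(self.lam) * np.sin(self.mu)
        z = f * np.cosh(self.lam) * np.cos(self.mu)
        p = np.array([rho * np.cos(self.theta), rho * np.sin(self.theta), z])
        if frame is not None:
            p = np.asarray(frame) @ p
        return p


def prolate_coordinates(point, focus, frame=None) -> ProlateCoords:
    """Cartesian -> prolate spheroidal (lambda, mu, theta).

    ``frame`` is an orthonormal triad (columns) whose third axis is the
    long axis; the point is expressed in that frame first.  Points on the
    long axis get theta = 0 by convention (and mu = 0 or pi depending on
    the side).  Round-trip accuracy is at the 1e-12 level away from the
    focal segment.
    """
    if focus <= 0:
        raise ValueError("focus must be positive")
    p = np.asarray(point, dtype=float)
    if frame is not None:
        p = np.asarray(frame).T @ p
    x, y, z = p
    rho = np.hypot(x, y)
    w = (z + 1j * rho) / focus
    u = np.arccosh(w)            # u = lam + i*mu with lam >= 0, mu in [0, pi]
    lam, mu = float(np.real(u)), float(np.imag(u))
    theta = float(np.arctan2(y, x)) if rho > 1e-14 else 0.0
    if rho <= 1e-14:
        mu = 0.0 if z >= 0 else np.pi
    return ProlateCoords(lam=lam, mu=mu, theta=theta, focus=focus)


# ---------------------------------------------------------------------------
# mesh construction


def build_idealized_biventricular(cfg: GeometryConfig | None = None) -> Mesh:
    """Generate the idealized biventricular hexahedral mesh.

    Deterministic: identical configs give bitwise-identical coordinates.
    Raises :class:`GeometryError` for degenerate dimensions.
    """
    cfg = cfg or GeometryConfig()
    nC, nL, nT, nTR = cfg.n_circ, cfg.n_long, cfg.n_trans, cfg.n_trans_rv
    i0, i1 = cfg._i_rv
    jR = cfg._j_rv
    dtheta = 2 * np.pi / nC
    mus = _ring_mus(cfg)  # mus[0] = base plane; pole handled separately

    nodes = []
    node_param = []  # (theta, mu, d, wall) for bookkeeping only

    def add_node(xyz, theta, mu, d, wall):
        nodes.append(xyz)
        node_param.append((theta, mu, d, wall))
        return len(nodes) - 1

    # LV shell nodes -------------------------------------------------------
    lv_id = np.empty((nC, nL + 1, nT + 1), dtype=int)
    for i in range(nC):
        th = i * dtheta
        for j in range(nL + 1):
            for k in range(nT + 1):
                d = k / nT
                lv_id[i, j, k] = add_node(
                    lv_wall_point(cfg, th, mus[j], d), th, mus[j], d, WALL_LV)
    pole_id = np.empty(nT + 1, dtype=int)
    for k in range(nT + 1):
        d = k / nT
        pole_id[k] = add_node(lv_wall_point(cfg, 0.0, np.pi, d),
                              0.0, np.pi, d, WALL_LV)

    # RV shell nodes -------------------------------------------------------
    rv_id = np.empty((i1 - i0 + 1, jR + 1, nTR + 1), dtype=int)
    for ii in range(i0, i1 + 1):
        th = ii * dtheta
        for j in range(jR + 1):
            for m in range(nTR + 1):
                d = 1.0 - m / nTR
                on_junction = (ii == i0 or ii == i1 or j == jR)
                if m == 0 and on_junction:
                    # weld: zero-bulge endocardial nodes sit on the LV epi
                    rv_id[ii - i0, j, m] = lv_id[ii % nC, j, 0]
                else:
                    rv_id[ii - i0, j, m] = add_node(
                        rv_wall_point(cfg, th, mus[j], d),
                        th, mus[j], d, WALL_RV)

    nodes = np.asarray(nodes, dtype=float)

    # elements -------------------------------------------------------------
    elems, region, e_param, e_wall = [], [], [], []

    def add_elem(conn, par, reg, wall):
        elems.append(conn)
        e_param.append(par)
        region.append(reg)
        e_wall.append(wall)

    for i in range(nC):
        ip = (i + 1) % nC
        th0, th1 = i * dtheta, (i + 1) * dtheta  # unwrapped
        septal_i = i0 <= i < i1
        for j in range(nL):
            reg = REGION_SEPTUM if (septal_i and j < jR) else REGION_LV_FREE_WALL
            for k in range(nT):
                d0, d1 = k / nT, (k + 1) / nT
                conn = [lv_id[i, j, k], lv_id[ip, j, k],
                        lv_id[ip, j + 1, k], lv_id[i, j + 1, k],
                        lv_id[i, j, k + 1], lv_id[ip, j, k + 1],
                        lv_id[ip, j + 1, k + 1], lv_id[i, j + 1, k + 1]]
                par = [(th0, mus[j], d0), (th1, mus[j], d0),
                       (th1, mus[j + 1], d0), (th0, mus[j + 1], d0),
                       (th0, mus[j], d1), (th1, mus[j], d1),
                       (th1, mus[j + 1], d1), (th0, mus[j + 1], d1)]
                add_elem(conn, par, reg, WALL_LV)
        # apex cap: collapsed hexes (wedges) from last ring to the pole
        j = nL
        for k in range(nT):
            d0, d1 = k / nT, (k + 1) / nT
            conn = [lv_id[i, j, k], lv_id[ip, j, k], pole_id[k], pole_id[k],
                    lv_id[i, j, k + 1], lv_id[ip, j, k + 1],
                    pole_id[k + 1], pole_id[k + 1]]
            par = [(th0, mus[j], d0), (th1, mus[j], d0),
                   (th1, np.pi, d0), (th0, np.pi, d0),
                   (th0, mus[j], d1), (th1, mus[j], d1),
                   (th1, np.pi, d1), (th0, np.pi, d1)]
            add_elem(conn, par, REGION_LV_FREE_WALL, WALL_LV)

    for ii in range(i0, i1):
        th0, th1 = ii * dtheta, (ii + 1) * dtheta
        a = ii - i0
        for j in range(jR):
            for m in range(nTR):
                d0, d1 = 1.0 - m / nTR, 1.0 - (m + 1) / nTR
                conn = [rv_id[a, j, m], rv_id[a + 1, j, m],
                        rv_id[a + 1, j + 1, m], rv_id[a, j + 1, m],
                        rv_id[a, j, m + 1], rv_id[a + 1, j, m + 1],
                        rv_id[a + 1, j + 1, m + 1], rv_id[a, j + 1, m + 1]]
                par = [(th0, mus[j], d0), (th1, mus[j], d0),
                       (th1, mus[j + 1], d0), (th0, mus[j + 1], d0),
                       (th0, mus[j], d1), (th1, mus[j], d1),
                       (th1, mus[j + 1], d1), (th0, mus[j + 1], d1)]
                add_elem(conn, par, REGION_RV_FREE_WALL, WALL_RV)

    elements = np.asarray(elems, dtype=int)
    element_region = np.asarray(region, dtype=int)
    elem_param = np.asarray(e_param, dtype=float)
    elem_wall = np.asarray(e_wall, dtype=int)

    # fix element orientation: positive Jacobian everywhere ----------------
    elements_orig = elements.copy()  # surface extraction uses builder's faces
    coords = nodes[elements]
    pts, _ = el.gauss_points(2)
    _, detJ = el.jacobians(coords, el.dshape(pts))
    flip = np.all(detJ < 0, axis=1)
    if np.any(flip):
        perm = [4, 5, 6, 7, 0, 1, 2, 3]
        elements[flip] = elements[flip][:, perm]
        elem_param[flip] = elem_param[flip][:, perm]
        coords = nodes[elements]
        _, detJ = el.jacobians(coords, el.dshape(pts))
    if np.any(detJ <= 0):
        bad = np.unique(np.where(detJ <= 0)[0])
        raise GeometryError(
            f"degenerate geometry: non-positive Jacobian in elements {bad[:5]}"
            " (RV shell likely self-intersecting; reduce rv_bulge or refine)")

    # surfaces -------------------------------------------------------------
    surfaces = {n: [] for n in ("LV_ENDO", "RV_ENDO", "EPI", "BASE")}
    owners = {n: [] for n in surfaces}

    def face_nodes(e, name, surf):
        owners[surf].append(e)
        return [elements_orig[e][a] for a in el.HEX_FACES[name]]

    eidx = 0
    for i in range(nC):
        septal_i = i0 <= i < i1
        for j in range(nL):
            for k in range(nT):
                if k == nT - 1:
                    surfaces["LV_ENDO"].append(
                        face_nodes(eidx, "zeta+", "LV_ENDO"))
                if k == 0:
                    name = "RV_ENDO" if (septal_i and j < jR) else "EPI"
                    surfaces[name].append(face_nodes(eidx, "zeta-", name))
                if j == 0:
                    surfaces["BASE"].append(face_nodes(eidx, "eta-", "BASE"))
                eidx += 1
        for k in range(nT):  # apex cap
            if k == nT - 1:
                surfaces["LV_ENDO"].append(
                    face_nodes(eidx, "zeta+", "LV_ENDO"))
            if k == 0:
                surfaces["EPI"].append(face_nodes(eidx, "zeta-", "EPI"))
            eidx += 1
    for ii in range(i0, i1):
        for j in range(jR):
            for m in range(nTR):
                if m == 0:
                    surfaces["RV_ENDO"].append(
                        face_nodes(eidx, "zeta-", "RV_ENDO"))
                if m == nTR - 1:
                    surfaces["EPI"].append(face_nodes(eidx, "zeta+", "EPI"))
                if j == 0:
                    surfaces["BASE"].append(face_nodes(eidx, "eta-", "BASE"))
                if j == jR - 1:
                    surfaces["EPI"].append(face_nodes(eidx, "eta+", "EPI"))
                if ii == i0:
                    surfaces["EPI"].append(face_nodes(eidx, "xi-", "EPI"))
                if ii == i1 - 1:
                    surfaces["EPI"].append(face_nodes(eidx, "xi+", "EPI"))
                eidx += 1

    surfaces = {k: np.asarray(v, dtype=int).reshape(-1, 4)
                for k, v in surfaces.items()}

    # orient all facets solid-outward (away from the owning element centroid)
    ecent = coords.mean(axis=1)
    for name, facets in surfaces.items():
        if len(facets) == 0:
            continue
        fc = nodes[facets].mean(axis=1)
        fn = _facet_normals(nodes, facets)
        own = np.asarray(owners[name], dtype=int)
        inward = np.einsum("fi,fi->f", fn, ecent[own] - fc) > 0
        facets[inward] = facets[inward][:, ::-1]

    # cavity facet sets: reverse solid-outward endo facets so their normals
    # point out of the blood pool
    cavity_facets = {"LV": surfaces["LV_ENDO"][:, ::-1].copy(),
                     "RV": surfaces["RV_ENDO"][:, ::-1].copy()}

    # cavity caps at the base plane
    lv_ring = np.array([lv_id[i, 0, nT] for i in range(nC)])
    rv_inner = np.array([lv_id[ii % nC, 0, 0] for ii in range(i0, i1 + 1)])
    rv_outer = np.array([rv_id[ii - i0, 0, 0] for ii in range(i0, i1 + 1)])
    cavity_caps = {"LV": lv_ring, "RV": (rv_inner, rv_outer)}

    base_nodes = np.unique(surfaces["BASE"])
    markers = {
        "junction_ant": int(lv_id[i0 % nC, 0, 0]),
        "junction_post": int(lv_id[i1 % nC, 0, 0]),
        "septum_mid": int(lv_id[((i0 + i1) // 2) % nC, 0, 0]),
    }

    mesh = Mesh(nodes=nodes, elements=elements, element_region=element_region,
                surfaces=surfaces, cavity_facets=cavity_facets,
                cavity_caps=cavity_caps, elem_param=elem_param,
                elem_wall=elem_wall, annulus_nodes=lv_ring,
                base_nodes=base_nodes, markers=markers, config=cfg)

    for cav in ("LV", "RV"):
        v = cavity_volume(mesh, None, cav)
        if v <= 0:
            raise GeometryError(f"non-positive {cav} cavity volume {v:.1f}")
    return mesh


def _facet_normals(nodes, facets):
    p = nodes[facets]
    n = np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1])
    return n


def _cap_triangles(mesh, x, cavity):
    """Deformed cap triangles (k, 3, 3) closing a cavity at the base."""
    if cavity == "LV":
        ring = x[mesh.cavity_caps["LV"]]
        c = ring.mean(axis=0)
        nxt = np.roll(ring, -1, axis=0)
        return np.stack([np.broadcast_to(c, ring.shape), ring, nxt], axis=1)
    inner, outer = mesh.cavity_caps["RV"]
    pi_, po = x[inner], x[outer]
    tris = []
    for t in range(len(inner) - 1):
        tris.append([pi_[t], po[t + 1], pi_[t + 1]])
        tris.append([pi_[t], po[t], po[t + 1]])
    return np.asarray(tris)


def cavity_volume(mesh: Mesh, displacement, cavity: str) -> float:
    """Cavity blood-pool volume (ml) via the divergence theorem.

    Integrates (1/3) x . n over the deformed endocardial facets plus the
    planar base cap; orientation is out of the cavity.  Invariant under
    rigid displacement of the whole model.
    """
    if cavity not in mesh.cavity_facets:
        raise KeyError(f"unknown cavity {cavity!r}; have "
                       f"{sorted(mesh.cavity_facets)}")
    x = mesh.nodes if displacement is None else mesh.nodes + displacement
    facets = mesh.cavity_facets[cavity]
    p = x[facets]
    # split each quad into two triangles; signed tet volume about origin
    tris = np.concatenate([p[:, [0, 1, 2]], p[:, [0, 2, 3]],
                           _cap_triangles(mesh, x, cavity)], axis=0)
    vol6 = np.einsum("ti,ti->t", tris[:, 0],
                     np.cross(tris[:, 1], tris[:, 2])).sum()
    # closure check: net normal area of a closed surface vanishes
    areas = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    net = areas.sum(axis=0)
    scale = np.linalg.norm(areas, axis=1).sum()
    if np.linalg.norm(net) > 1e-8 * max(scale, 1.0):
        raise TopologyError(
            f"{cavity} cavity surface is not closed (net area {net})")
    return vol6 / 6.0 / 1000.0


def analytic_lv_cavity_volume(cfg: GeometryConfig) -> float:
    """Closed-form volume (ml) of the truncated endocardial ellipsoid
    segment the LV cavity discretizes (from the base-truncation plane to
    the apex)."""
    R, C = cfg.lv_endo_radius, cfg.lv_endo_apex
    zb = C * np.cos(cfg.mu_base)
    vol = np.pi * R * R / (C * C) * (
        C * C * zb - zb ** 3 / 3.0 + 2.0 / 3.0 * C ** 3)
    return vol / 1000.0
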