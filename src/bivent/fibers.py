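"""Rule-based myofiber and sheet architecture.

The fiber direction lies in the local circumferential-longitudinal plane,
rotated from the circumferential unit vector by a helix angle that varies
linearly with normalized transmural depth d, from ``epi_angle`` on the
epicardium (d = 0) to ``endo_angle`` on the endocardium (d = 1).  The same
rule is applied to the LV free wall, the septum (depth running from the
RV-facing to the LV-facing surface) and the RV free wall.  Sheets are
taken normal to the endo/epicardial surfaces (the transmural direction),
so (f0, s0, n0) is an orthonormal triad at every quadrature point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import elements as el
from .geometry import GeometryConfig, Mesh, WALL_LV, lv_wall_point, \
    rv_wall_point

log = logging.getLogger(__name__)


@dataclass
class FiberField:
    """Orthonormal fiber/sheet/normal triads at element quadrature points.

    Arrays have shape (n_elements, n_points, 3); ``helix_angle`` is in
    degrees, shape (n_elements, n_points).
    """

    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray
    helix_angle: np.ndarray
    local_points: np.ndarray  # the element-local coordinates used


def _wall_derivatives(cfg: GeometryConfig, wall, theta, mu, d, h=1e-5):
    fn = lv_wall_point if wall == WALL_LV else rv_wall_point
    e_c = (fn(cfg, theta + h, mu, d) - fn(cfg, theta - h, mu, d)) / (2 * h)
    e_l = (fn(cfg, theta, mu + h, d) - fn(cfg, theta, mu - h, d)) / (2 * h)
    return e_c, e_l


def assign_fiber_sheet(mesh: Mesh, epi_angle: float = -60.0,
                       endo_angle: float = 60.0,
                       local_points: np.ndarray | None = None) -> FiberField:
    """Evaluate the fiber rule at element quadrature points.

    ``local_points``: (G, 3) element-local coordinates; defaults to the
    2x2x2 Gauss set.  Points where the circumferential direction is
    numerically degenerate (at the apex pole) fall back to the triad of
    the nearest well-defined point in the same element, and the fallback
    is logged.
    """
    if local_points is None:
        local_points, _ = el.gauss_points(2)
    N = el.shape(local_points)                      # (G, 8)
    par = np.einsum("ga,eap->egp", N, mesh.elem_param)  # (E, G, 3)
    theta, mu, d = par[..., 0], par[..., 1], par[..., 2]
    cfg = mesh.config

    E, G = theta.shape
    e_c = np.empty((E, G, 3))
    e_l = np.empty((E, G, 3))
    for wall in np.unique(mesh.elem_wall):
        sel = mesh.elem_wall == wall
        ec, elg = _wall_derivatives(cfg, wall, theta[sel], mu[sel], d[sel])
        e_c[sel], e_l[sel] = ec, elg

    nc = np.linalg.norm(e_c, axis=-1)
    degenerate = nc < 1e-8 * np.median(nc)
    if np.any(degenerate):
        log.info("fiber rule: %d degenerate circumferential points near the "
                 "apex replaced by nearest-neighbor triads",
                 int(degenerate.sum()))
    nc_safe = np.where(degenerate, 1.0, nc)
    e_c = e_c / nc_safe[..., None]
    # Gram-Schmidt: longitudinal orthogonal to circumferential
    e_l = e_l - np.einsum("egi,egi->eg", e_l, e_c)[..., None] * e_c
    e_l = e_l / np.linalg.norm(e_l, axis=-1, keepdims=True)
    e_t = np.cross(e_c, e_l)  # transmural, toward increasing depth

    helix = epi_angle + d * (endo_angle - epi_angle)
    a = np.deg2rad(helix)[..., None]
    f0 = np.cos(a) * e_c + np.sin(a) * e_l
    s0 = e_t
    n0 = np.cross(f0, s0)

    if np.any(degenerate):
        # replace degenerate points by the nearest valid point's triad
        for e, g in zip(*np.where(degenerate)):
            valid = np.where(~degenerate[e])[0]
            if len(valid) == 0:
                raise ValueError(f"element {e} has no valid fiber points")
            j = valid[np.argmin(np.abs(valid - g))]
            f0[e, g], s0[e, g], n0[e, g] = f0[e, j], s0[e, j], n0[e, j]
            helix[e, g] = helix[e, j]

    return FiberField(f0=f0, s0=s0, n0=n0, helix_angle=helix,
                      local_points=np.asarray(local_points))
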