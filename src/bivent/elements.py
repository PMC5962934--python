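"""Trilinear hexahedral element utilities shared by geometry and FE code.

Local coordinates (xi, eta, zeta) in [-1, 1]^3, node ordering follows the
VTK hexahedron convention: nodes 0-3 on the zeta = -1 face (counter-
clockwise), nodes 4-7 above them on zeta = +1.
"""

from __future__ import annotations

import numpy as np

# local node coordinates, VTK ordering
HEX_LOCAL = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)

_G = 1.0 / np.sqrt(3.0)


def gauss_points(order: int = 2):
    """Tensor-product Gauss points and weights for the hex (order 1 or 2)."""
    if order == 1:
        return np.zeros((1, 3)), np.array([8.0])
    if order == 2:
        pts = np.array([[sx * _G, sy * _G, sz * _G]
                        for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
        return pts, np.full(8, 1.0)
    raise ValueError("quadrature order must be 1 or 2")


def shape(xi):
    """Trilinear shape functions N_a(xi), shape (..., 8)."""
    xi = np.asarray(xi, dtype=float)
    out = np.empty(xi.shape[:-1] + (8,))
    for a in range(8):
        la = HEX_LOCAL[a]
        out[..., a] = 0.125 * (1 + la[0] * xi[..., 0]) \
            * (1 + la[1] * xi[..., 1]) * (1 + la[2] * xi[..., 2])
    return out


def dshape(xi):
    """Shape-function gradients dN_a/dxi_j, shape (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    out = np.empty(xi.shape[:-1] + (8, 3))
    for a in range(8):
        la = HEX_LOCAL[a]
        fx = 1 + la[0] * xi[..., 0]
        fy = 1 + la[1] * xi[..., 1]
        fz = 1 + la[2] * xi[..., 2]
        out[..., a, 0] = 0.125 * la[0] * fy * fz
        out[..., a, 1] = 0.125 * la[1] * fx * fz
        out[..., a, 2] = 0.125 * la[2] * fx * fy
    return out


def jacobians(coords, dN):
    """Jacobian dx/dxi at quadrature points.

    coords: (nelem, 8, 3) nodal coordinates
    dN:     (ngp, 8, 3) local shape gradients
    returns J (nelem, ngp, 3, 3), detJ (nelem, ngp)
    """
    J = np.einsum("gad,eai->egdi", dN, coords).swapaxes(-1, -2)
    # J[e,g,i,d] = sum_a dN[g,a,d] coords[e,a,i]
    detJ = np.linalg.det(J)
    return J, detJ


def element_volumes(coords):
    """Exact trilinear element volumes via 2x2x2 quadrature."""
    pts, w = gauss_points(2)
    dN = dshape(pts)
    _, detJ = jacobians(coords, dN)
    return np.einsum("g,eg->e", w, detJ)


# bilinear quad facets ------------------------------------------------------

QUAD_LOCAL = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)


def quad_gauss():
    pts = np.array([[sx * _G, sy * _G] for sy in (-1, 1) for sx in (-1, 1)])
    return pts, np.full(4, 1.0)


def quad_shape(xi):
    xi = np.asarray(xi, dtype=float)
    out = np.empty(xi.shape[:-1] + (4,))
    for a in range(4):
        la = QUAD_LOCAL[a]
        out[..., a] = 0.25 * (1 + la[0] * xi[..., 0]) * (1 + la[1] * xi[..., 1])
    return out


def quad_dshape(xi):
    xi = np.asarray(xi, dtype=float)
    out = np.empty(xi.shape[:-1] + (4, 2))
    for a in range(4):
        la = QUAD_LOCAL[a]
        out[..., a, 0] = 0.25 * la[0] * (1 + la[1] * xi[..., 1])
        out[..., a, 1] = 0.25 * la[1] * (1 + la[0] * xi[..., 0])
    return out


# faces of the hex in VTK ordering, outward-facing node order
HEX_FACES = {
    "zeta-": (0, 3, 2, 1),
    "zeta+": (4, 5, 6, 7),
    "eta-": (0, 1, 5, 4),
    "eta+": (3, 7, 6, 2),
    "xi-": (0, 4, 7, 3),
    "xi+": (1, 2, 6, 5),
}
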