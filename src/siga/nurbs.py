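"""NURBS geometric kernel: B-spline basis, rational surface evaluation, quadrature.

Surfaces are tensor-product NURBS patches

    S(xi, eta) = sum_ij R_ij(xi, eta) b_ij,
    R_ij = N_i,p(xi) M_j,q(eta) w_ij / sum_kl N_k,p M_l,q w_kl,

with open knot vectors on [0, 1], evaluated with the Cox-de Boor recursion.
Derivatives up to second order are supplied for the active-surface energy and
for the surface Jacobians used by the divergence-theorem integrals.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NurbsPatch",
    "QuadratureRule",
    "open_uniform_knots",
    "bspline_basis",
    "basis_derivatives",
    "gauss_legendre",
    "patch_area",
    "tessellate",
    "save_patches",
    "load_patches",
    "write_obj",
]


def open_uniform_knots(n_ctrl: int, degree: int) -> np.ndarray:
    """Open (clamped) uniform knot vector on [0, 1] for ``n_ctrl`` basis functions."""
    if n_ctrl < degree + 1:
        raise ValueError(f"need at least degree+1={degree + 1} control points, got {n_ctrl}")
    n_interior = n_ctrl - degree - 1
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    return np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])


def _find_spans(knots: np.ndarray, degree: int, u: np.ndarray) -> np.ndarray:
    n_basis = len(knots) - degree - 1
    spans = np.searchsorted(knots, u, side="right") - 1
    return np.clip(spans, degree, n_basis - 1)


def basis_derivatives(knots: np.ndarray, degree: int, u, nderiv: int = 0):
    """Nonzero B-spline basis values and derivatives at parameters ``u``.

    Returns ``(spans, ders)`` with ``spans`` of shape ``(m,)`` and ``ders`` of
    shape ``(nderiv+1, m, degree+1)``; ``ders[k, t, i]`` is the k-th derivative
    of basis function ``spans[t]-degree+i`` at ``u[t]``.  Vectorized Cox-de Boor
    / derivative recursion (loops only over the degree).
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any(u < knots[0] - 1e-12) or np.any(u > knots[-1] + 1e-12):
        raise ValueError("parameter outside knot range")
    u = np.clip(u, knots[0], knots[-1])
    m = u.shape[0]
    p = degree
    spans = _find_spans(knots, p, u)

    # ndu[j, r, t]: triangular table of basis values and knot differences
    ndu = np.zeros((p + 1, p + 1, m))
    ndu[0, 0] = 1.0
    left = np.zeros((p + 1, m))
    right = np.zeros((p + 1, m))
    for j in range(1, p + 1):
        left[j] = u - knots[spans + 1 - j]
        right[j] = knots[spans + j] - u
        saved = np.zeros(m)
        for r in range(j):
            ndu[j, r] = right[r + 1] + left[j - r]
            with np.errstate(divide="ignore", invalid="ignore"):
                temp = np.where(ndu[j, r] > 0, ndu[r, j - 1] / np.where(ndu[j, r] == 0, 1, ndu[j, r]), 0.0)
            ndu[r, j] = saved + right[r + 1] * temp
            saved = left[j - r] * temp
        ndu[j, j] = saved

    ders = np.zeros((nderiv + 1, m, p + 1))
    ders[0] = ndu[: p + 1, p].T  # N_{span-p+r, p}(u) = ndu[r, p]

    if nderiv > 0:
        a = np.zeros((2, p + 1, m))
        for r in range(p + 1):
            s1, s2 = 0, 1
            a[0, 0] = 1.0
            a[1] = 0.0
            for k in range(1, min(nderiv, p) + 1):
                d = np.zeros(m)
                rk = r - k
                pk = p - k
                if r >= k:
                    a[s2, 0] = a[s1, 0] / ndu[pk + 1, rk]
                    d = a[s2, 0] * ndu[rk, pk]
                j1 = 1 if rk >= -1 else -rk
                j2 = k - 1 if r - 1 <= pk else p - r
                for j in range(j1, j2 + 1):
                    a[s2, j] = (a[s1, j] - a[s1, j - 1]) / ndu[pk + 1, rk + j]
                    d = d + a[s2, j] * ndu[rk + j, pk]
                if r <= pk:
                    a[s2, k] = -a[s1, k - 1] / ndu[pk + 1, r]
                    d = d + a[s2, k] * ndu[r, pk]
                ders[k, :, r] = d
                s1, s2 = s2, s1
        r_fact = float(p)
        for k in range(1, min(nderiv, p) + 1):
            ders[k] *= r_fact
            r_fact *= p - k
        # derivatives of order > p are identically zero (already zeros)
    return spans, ders


def bspline_basis(knots, degree: int, u: float) -> np.ndarray:
    """The ``degree+1`` nonzero B-spline basis values at ``u`` (partition of unity)."""
    knots = np.asarray(knots, dtype=float)
    _, ders = basis_derivatives(knots, degree, [u], 0)
    return ders[0, 0]


@dataclass
class NurbsPatch:
    """Tensor-product NURBS surface patch with open knot vectors on [0, 1]^2.

    control has shape (n_u, n_v, 3) in mm; weights (n_u, n_v), all positive.
    The u direction is conventionally the circumferential coordinate xi and
    v the axial coordinate eta.
    """

    degree_u: int
    degree_v: int
    knots_u: np.ndarray
    knots_v: np.ndarray
    control: np.ndarray
    weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.knots_u = np.asarray(self.knots_u, dtype=float)
        self.knots_v = np.asarray(self.knots_v, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        if self.weights is None:
            self.weights = np.ones(self.control.shape[:2])
        self.weights = np.asarray(self.weights, dtype=float)
        nu, nv = self.control.shape[:2]
        if len(self.knots_u) != nu + self.degree_u + 1:
            raise ValueError("knots_u inconsistent with control net")
        if len(self.knots_v) != nv + self.degree_v + 1:
            raise ValueError("knots_v inconsistent with control net")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    @property
    def shape(self):
        return self.control.shape[:2]

    def evaluate(self, xi, eta, nderiv: int = 0) -> dict:
        """Evaluate the surface and parametric derivatives at paired (xi, eta).

        Returns a dict with key "S" (shape ``xi.shape + (3,)``) and, for
        ``nderiv >= 1``, "S_xi", "S_eta"; for ``nderiv == 2`` additionally
        "S_xixi", "S_xieta", "S_etaeta".  Rational derivative formulas are
        used; with all-equal weights they reduce to plain B-spline results.
        """
        if nderiv > 2:
            raise ValueError("derivative order > 2 unsupported")
        xi = np.asarray(xi, dtype=float)
        eta = np.asarray(eta, dtype=float)
        shape = np.broadcast_shapes(xi.shape, eta.shape)
        xi_f = np.broadcast_to(xi, shape).ravel()
        eta_f = np.broadcast_to(eta, shape).ravel()

        p, q = self.degree_u, self.degree_v
        su, du = basis_derivatives(self.knots_u, p, xi_f, nderiv)
        sv, dv = basis_derivatives(self.knots_v, q, eta_f, nderiv)

        # homogeneous control points
        Pw = np.concatenate([self.control * self.weights[..., None], self.weights[..., None]], axis=-1)
        iu = su[:, None] - p + np.arange(p + 1)[None, :]
        iv = sv[:, None] - q + np.arange(q + 1)[None, :]
        local = Pw[iu[:, :, None], iv[:, None, :], :]  # (m, p+1, q+1, 4)

        def A(k, l):
            return np.einsum("mi,mj,mijc->mc", du[k], dv[l], local)

        out = {}
        A00 = A(0, 0)
        w = A00[:, 3:4]
        S = A00[:, :3] / w
        out["S"] = S
        if nderiv >= 1:
            A10, A01 = A(1, 0), A(0, 1)
            Su = (A10[:, :3] - A10[:, 3:4] * S) / w
            Sv = (A01[:, :3] - A01[:, 3:4] * S) / w
            out["S_xi"], out["S_eta"] = Su, Sv
        if nderiv == 2:
            A20, A02, A11 = A(2, 0), A(0, 2), A(1, 1)
            w10, w01 = A10[:, 3:4], A01[:, 3:4]
            Suu = (A20[:, :3] - 2 * w10 * Su - A20[:, 3:4] * S) / w
            Svv = (A02[:, :3] - 2 * w01 * Sv - A02[:, 3:4] * S) / w
            Suv = (A11[:, :3] - w10 * Sv - w01 * Su - A11[:, 3:4] * S) / w
            out["S_xixi"], out["S_xieta"], out["S_etaeta"] = Suu, Suv, Svv
        return {k: v.reshape(shape + (3,)) for k, v in out.items()}

    def basis_matrix(self, xi, eta, nderiv: int = 0):
        """Basis-function design matrices at paired (xi, eta).

        Returns a dict mapping derivative keys ("R", "R_xi", ...) to dense
        arrays of shape (m, n_u * n_v) with basis index ``i * n_v + j``.
        Valid for unit weights (the template construction used here); rational
        weighting is handled in :meth:`evaluate`.
        """
        xi = np.atleast_1d(np.asarray(xi, dtype=float)).ravel()
        eta = np.atleast_1d(np.asarray(eta, dtype=float)).ravel()
        p, q = self.degree_u, self.degree_v
        nu, nv = self.shape
        su, du = basis_derivatives(self.knots_u, p, xi, nderiv)
        sv, dv = basis_derivatives(self.knots_v, q, eta, nderiv)
        m = xi.shape[0]
        iu = su[:, None] - p + np.arange(p + 1)[None, :]
        iv = sv[:, None] - q + np.arange(q + 1)[None, :]
        cols = (iu[:, :, None] * nv + iv[:, None, :]).reshape(m, -1)
        keys = [("R", 0, 0)]
        if nderiv >= 1:
            keys += [("R_xi", 1, 0), ("R_eta", 0, 1)]
        if nderiv >= 2:
            keys += [("R_xixi", 2, 0), ("R_xieta", 1, 1), ("R_etaeta", 0, 2)]
        out = {}
        for name, k, l in keys:
            vals = (du[k][:, :, None] * dv[l][:, None, :]).reshape(m, -1)
            mat = np.zeros((m, nu * nv))
            np.put_along_axis(mat, cols, vals, axis=1)
            out[name] = mat
        return out


@dataclass
class QuadratureRule:
    """Tensor Gauss-Legendre rule over the knot spans of a patch domain."""

    points: np.ndarray  # (N, 2) in [0,1]^2
    weights: np.ndarray  # (N,)


def gauss_legendre(patch: NurbsPatch, order: int = 4) -> QuadratureRule:
    """Gauss-Legendre quadrature with ``order`` points per direction per knot span."""
    if order < 1:
        raise ValueError("order must be >= 1")
    g, gw = np.polynomial.legendre.leggauss(order)

    def per_direction(knots):
        spans = np.unique(knots)
        pts, wts = [], []
        for a, b in zip(spans[:-1], spans[1:]):
            pts.append(0.5 * (b - a) * (g + 1) + a)
            wts.append(0.5 * (b - a) * gw)
        return np.concatenate(pts), np.concatenate(wts)

    pu, wu = per_direction(patch.knots_u)
    pv, wv = per_direction(patch.knots_v)
    P = np.stack([np.repeat(pu, len(pv)), np.tile(pv, len(pu))], axis=1)
    W = (wu[:, None] * wv[None, :]).ravel()
    return QuadratureRule(points=P, weights=W)


def patch_area(patch: NurbsPatch, order: int = 4) -> float:
    """Surface area of a patch, integral of |S_xi x S_eta| by Gauss quadrature."""
    rule = gauss_legendre(patch, order)
    d = patch.evaluate(rule.points[:, 0], rule.points[:, 1], nderiv=1)
    jac = np.linalg.norm(np.cross(d["S_xi"], d["S_eta"]), axis=-1)
    return float(np.dot(rule.weights, jac))


def tessellate(patch: NurbsPatch, n_u: int = 24, n_v: int = 24):
    """Triangulate a patch on a uniform parametric grid; returns (vertices, faces)."""
    u = np.linspace(0, 1, n_u + 1)
    v = np.linspace(0, 1, n_v + 1)
    U, V = np.meshgrid(u, v, indexing="ij")
    pts = patch.evaluate(U, V)["S"].reshape(-1, 3)
    faces = []
    for i in range(n_u):
        for j in range(n_v):
            a = i * (n_v + 1) + j
            b = a + (n_v + 1)
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return pts, np.asarray(faces, dtype=np.int64)


def save_patches(patches, path):
    """Serialize patches (degrees, knots, weights, control nets) to JSON."""
    payload = []
    for pa in patches:
        payload.append(
            {
                "degree_u": pa.degree_u,
                "degree_v": pa.degree_v,
                "knots_u": pa.knots_u.tolist(),
                "knots_v": pa.knots_v.tolist(),
                "control": pa.control.tolist(),
                "weights": pa.weights.tolist(),
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_patches(path):
    with open(path) as fh:
        payload = json.load(fh)
    return [
        NurbsPatch(
            degree_u=d["degree_u"],
            degree_v=d["degree_v"],
            knots_u=np.asarray(d["knots_u"]),
            knots_v=np.asarray(d["knots_v"]),
            control=np.asarray(d["control"]),
            weights=np.asarray(d["weights"]),
        )
        for d in payload
    ]


def write_obj(patches, path, n_u: int = 24, n_v: int = 24):
    """Export tessellated patches as a Wavefront OBJ file for inspection."""
    with open(path, "w") as fh:
        offset = 1
        for pa in patches:
            V, F = tessellate(pa, n_u, n_v)
            for p in V:
                fh.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            for f in F:
                fh.write(f"f {f[0] + offset} {f[1] + offset} {f[2] + offset}\n")
            offset += len(V)
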