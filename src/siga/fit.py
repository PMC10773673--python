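"""Active-surface (Snakes) fitting of multi-patch NURBS tubes to binary masks.

Each airway branch is initialized as a sweep of octagonal control-point rings
along its centerline (rotation-minimizing frames) and evolved by the gradient
flow of the energy

    E(S) = alpha/2 int (|S_xi|^2 + |S_eta|^2)
         + beta/2  int (|S_xixi|^2 + |S_xieta|^2 + |S_etaeta|^2)
         - lambda/2 int |grad I_sigma(S)|^2,

discretized in space by two cubic NURBS patches per segment (C0 seams at the
shared control columns) and in fictitious time by a semi-implicit scheme: the
quadratic regularization is treated implicitly, the image force explicitly,
so every step solves one symmetric positive-definite linear system

    (M/dt + K) b+ = (M/dt) b + F(b).

Validation is by the DICE overlap between the input mask and the voxelization
of the fitted closed surfaces.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.linalg import cho_factor, cho_solve

from .image import BinaryImage, ForceField, ScalarField, edge_density, gaussian_smooth, image_force
from .nurbs import NurbsPatch, basis_derivatives, gauss_legendre, open_uniform_knots
from .skeleton import Branch, BranchGraph, Skeleton, build_branch_graph, merge_short_branches, skeletonize

__all__ = [
    "SigaParams",
    "BranchSurface",
    "FitSystem",
    "FitResult",
    "build_templates",
    "assemble",
    "evolve",
    "voxelize",
    "dice",
    "fit_mask",
]

N_COLS = 8  # octagonal template: 8 circumferential control points


@dataclass
class SigaParams:
    """Energy and discretization parameters of the Snakes fit.

    Defaults are the calibrated values used for the CT cohort: alpha=1e-2,
    beta=1e-3 (regularization), lam=0.1 (image energy), sigma=2 voxels
    (mask smoothing), dt=0.01 with at most 35 iterations, cubic patches,
    two patches per segment.
    """

    alpha: float = 1e-2
    beta: float = 1e-3
    lam: float = 0.1
    sigma: float = 2.0
    dt: float = 0.01
    max_iters: int = 35
    degree_p: int = 3
    degree_q: int = 3
    patches_per_segment: int = 2
    quad_order: int = 4
    tol: float = 1e-3  # mm, max control-point displacement

    def __post_init__(self):
        if min(self.alpha, self.beta, self.lam, self.dt) <= 0:
            raise ValueError("alpha, beta, lambda and dt must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.patches_per_segment != 2:
            raise ValueError("only the two-patch circumferential split is implemented")

    @classmethod
    def from_dict(cls, d: dict) -> "SigaParams":
        d = dict(d)
        if "lambda" in d:
            d["lam"] = d.pop("lambda")
        return cls(**d)


def _half_knots(degree: int) -> np.ndarray:
    # 5 control columns per half circumference
    return open_uniform_knots(N_COLS // 2 + 1, degree)


_COLMAPS = ([0, 1, 2, 3, 4], [4, 5, 6, 7, 0])


@lru_cache(maxsize=None)
def _octagon_correction(degree: int = 3) -> tuple:
    """Radial scale factors making the octagon control polygon trace a circle.

    The two clamped half-patches interpolate the seam control points, so a
    plain octagon of radius 1 yields a curve that oscillates below the unit
    circle between seams.  A small least-squares fit (shared unknowns at the
    seams, fixed spoke directions) brings the traced curve onto the circle to
    well under 1%.
    """
    ang = 2 * math.pi * np.arange(N_COLS) / N_COLS
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    knots = _half_knots(degree)
    u = np.linspace(0, 1, 200)
    spans, ders = basis_derivatives(knots, degree, u, 0)
    nb = N_COLS // 2 + 1
    B = np.zeros((len(u), nb))
    cols = spans[:, None] - degree + np.arange(degree + 1)[None, :]
    np.put_along_axis(B, cols, ders[0], axis=1)

    c = np.ones(N_COLS)
    for _ in range(4):
        rows, rhs = [], []
        for colmap in _COLMAPS:
            pts = B @ (c[list(colmap)][:, None] * dirs[list(colmap)])
            theta = np.arctan2(pts[:, 1], pts[:, 0])
            target = np.stack([np.cos(theta), np.sin(theta)], axis=1)
            for coord in range(2):
                A = np.zeros((len(u), N_COLS))
                for local, k in enumerate(colmap):
                    A[:, k] += B[:, local] * dirs[k, coord]
                rows.append(A)
                rhs.append(target[:, coord])
        c, *_ = np.linalg.lstsq(np.vstack(rows), np.concatenate(rhs), rcond=None)
    return tuple(c)


@lru_cache(maxsize=None)
def _ring_basis(degree: int, n_samples: int = 60):
    """Per-patch B-spline curve design matrix used by the ring fits."""
    knots = _half_knots(degree)
    u = np.linspace(0, 1, n_samples)
    spans, ders = basis_derivatives(knots, degree, u, 0)
    B = np.zeros((n_samples, N_COLS // 2 + 1))
    cols = spans[:, None] - degree + np.arange(degree + 1)[None, :]
    np.put_along_axis(B, cols, ders[0], axis=1)
    return B


def _fit_ring_radii(r_of_theta, rho_init: np.ndarray, degree: int) -> np.ndarray:
    """Control radii whose traced closed curve matches a radius profile.

    ``r_of_theta`` maps angle (rad) to target wall distance.  Solves a small
    least-squares problem (shared seam unknowns, fixed spoke directions) a few
    times, re-estimating the curve's angular parameterization between passes.
    This generalizes the circle correction to arbitrary star-shaped sections
    such as elliptic lumina.
    """
    ang = 2 * math.pi * np.arange(N_COLS) / N_COLS
    dirs2 = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    B = _ring_basis(degree)
    rho = rho_init.astype(float).copy()
    for _ in range(3):
        rows, rhs = [], []
        for colmap in _COLMAPS:
            pts = B @ (rho[list(colmap)][:, None] * dirs2[list(colmap)])
            theta = np.arctan2(pts[:, 1], pts[:, 0])
            target = r_of_theta(theta)
            for coord in range(2):
                A = np.zeros((B.shape[0], N_COLS))
                for local, k in enumerate(colmap):
                    A[:, k] += B[:, local] * dirs2[k, coord]
                rows.append(A)
                rhs.append(target * (np.cos(theta) if coord == 0 else np.sin(theta)))
        rho, *_ = np.linalg.lstsq(np.vstack(rows), np.concatenate(rhs), rcond=None)
    return rho


def _rotation_minimizing_frames(centers: np.ndarray):
    """Double-reflection frame transport along a polyline; returns (e1, e2, t)."""
    n = len(centers)
    t = np.gradient(centers, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    e1 = np.zeros_like(centers)
    seed = np.array([1.0, 0, 0])
    if abs(t[0] @ seed) > 0.9:
        seed = np.array([0, 1.0, 0])
    e1[0] = seed - (seed @ t[0]) * t[0]
    e1[0] /= np.linalg.norm(e1[0])
    for i in range(n - 1):
        v1 = centers[i + 1] - centers[i]
        c1 = v1 @ v1
        if c1 < 1e-14:
            e1[i + 1] = e1[i]
            continue
        rL = e1[i] - (2 / c1) * (v1 @ e1[i]) * v1
        tL = t[i] - (2 / c1) * (v1 @ t[i]) * v1
        v2 = t[i + 1] - tL
        c2 = v2 @ v2
        if c2 < 1e-14:
            e1[i + 1] = rL
        else:
            e1[i + 1] = rL - (2 / c2) * (v2 @ rL) * v2
        e1[i + 1] -= (e1[i + 1] @ t[i + 1]) * t[i + 1]
        e1[i + 1] /= np.linalg.norm(e1[i + 1])
    e2 = np.cross(t, e1)
    return e1, e2, t


@dataclass
class BranchSurface:
    """Two-patch NURBS mantle of one airway branch.

    The control net has shape (n_rings, 8, 3): octagonal rings along the
    branch.  The two patches split the circumference (columns 0-4 and 4-0
    wrapping), sharing the seam columns 0 and 4 so the mantle is C0 closed.
    """

    branch_id: int
    control: np.ndarray  # (n_rings, 8, 3)
    centers: np.ndarray  # (n_rings, 3) ring centers on the centerline
    degree_p: int = 3
    degree_q: int = 3

    @property
    def n_rings(self) -> int:
        return self.control.shape[0]

    @property
    def knots_xi(self) -> np.ndarray:
        return _half_knots(self.degree_p)

    @property
    def knots_eta(self) -> np.ndarray:
        return open_uniform_knots(self.n_rings, self.degree_q)

    def patches(self):
        """The two mantle patches (control shape (5, n_rings, 3) each)."""
        out = []
        for colmap in _COLMAPS:
            ctrl = np.transpose(self.control[:, colmap, :], (1, 0, 2))
            out.append(
                NurbsPatch(
                    degree_u=self.degree_p,
                    degree_v=self.degree_q,
                    knots_u=self.knots_xi,
                    knots_v=self.knots_eta,
                    control=ctrl,
                )
            )
        return out

    def dof_maps(self):
        """Global flat-DOF index (ring*8+col) for each patch-local basis index."""
        maps = []
        nv = self.n_rings
        for colmap in _COLMAPS:
            gm = np.empty(len(colmap) * nv, dtype=np.int64)
            for iu, col in enumerate(colmap):
                gm[iu * nv : (iu + 1) * nv] = np.arange(nv) * N_COLS + col
            maps.append(gm)
        return maps

    def copy(self) -> "BranchSurface":
        return BranchSurface(
            branch_id=self.branch_id,
            control=self.control.copy(),
            centers=self.centers.copy(),
            degree_p=self.degree_p,
            degree_q=self.degree_q,
        )


def _resample_polyline(nodes: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    si = np.linspace(0, s[-1], n)
    out = np.empty((n, 3))
    for c in range(3):
        out[:, c] = np.interp(si, s, nodes[:, c])
    return out


def _section_profile(localizer: ScalarField, center, e1, e2, step, smax, n_theta: int = 64):
    """Area-equivalent wall radius profile r(theta) of one cross-section.

    The (lightly smoothed) mask is sampled on a polar grid in the ring plane;
    at each angle the lumen area integral gives r(theta) = sqrt(2 int s ds).
    Integrating over area instead of intersecting single rays suppresses the
    half-voxel aliasing of the rasterized wall and averages out boundary
    noise.  Directions opening into a junction are capped at ``smax``.
    """
    theta = 2 * math.pi * (np.arange(n_theta) + 0.5) / n_theta
    n_s = max(8, int(math.ceil(smax / step)))
    s = smax * (np.arange(n_s) + 0.5) / n_s
    ds = smax / n_s
    dirs = np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2)  # (n_theta, 3)
    pts = center[None, None, :] + s[None, :, None] * dirs[:, None, :]
    inside = localizer.interp(pts.reshape(-1, 3)).reshape(n_theta, n_s) >= 0.5
    # per-angle area-equivalent radius: r(theta)^2 = 2 * int_0^r s ds
    r2 = 2.0 * (inside * s[None, :]).sum(axis=1) * ds
    return theta, np.sqrt(np.maximum(r2, 0.0))


LOCALIZER_SIGMA = 0.7  # voxels; sub-voxel smoothing for wall localization only


def build_templates(
    branch: Branch,
    image: BinaryImage | None = None,
    localizer: ScalarField | None = None,
    params: SigaParams | None = None,
    rings: int | None = None,
) -> BranchSurface:
    """Initial octagonal-template surface for one branch.

    Rings of 8 control points are centered on resampled skeleton nodes and
    oriented perpendicular to the centerline with rotation-minimizing frames.
    When the mask is available, each spoke radius is measured by ray marching
    to the wall (0.5 crossing of a lightly smoothed localization field), so
    non-circular lumina start close to the wall; otherwise the ring radius is
    the local skeleton radius.  Radii are corrected so the traced NURBS curve
    matches the target radius rather than the control polygon.
    """
    params = params or SigaParams()
    nodes = np.asarray(branch.nodes, dtype=float)
    radii = np.asarray(branch.radii, dtype=float)
    if len(nodes) < 2:
        raise ValueError("branch needs at least two nodes")
    r_med = float(np.median(radii))
    if r_med <= 0:
        fallback = float(min(image.spacing)) if image is not None else 1.0
        warnings.warn("branch has zero local radius; falling back to one voxel", stacklevel=2)
        radii = np.full_like(radii, fallback)
        r_med = fallback
    L = branch.length
    if rings is None:
        rings = max(4, int(math.ceil(L / r_med)) + 3)
    centers = _resample_polyline(nodes, rings)
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    s_nodes = np.concatenate([[0.0], np.cumsum(seg)])
    ring_r = np.interp(np.linspace(0, s_nodes[-1], rings), s_nodes, radii)
    e1, e2, t = _rotation_minimizing_frames(centers)

    if localizer is None and image is not None:
        localizer = gaussian_smooth(image, LOCALIZER_SIGMA)
    corr = np.asarray(_octagon_correction(params.degree_p))
    ang = 2 * math.pi * np.arange(N_COLS) / N_COLS
    control = np.empty((rings, N_COLS, 3))
    step = 0.3 * float(min(image.spacing)) if image is not None else 0.0
    spokes, frames = [], []
    for m in range(rings):
        dirs = np.outer(np.cos(ang), e1[m]) + np.outer(np.sin(ang), e2[m])
        if localizer is not None and image is not None:
            # nudge end-ring sampling centers inward so spokes start inside
            c = centers[m].copy()
            if m == 0:
                c = c + 0.5 * float(min(image.spacing)) * t[m]
            elif m == rings - 1:
                c = c - 0.5 * float(min(image.spacing)) * t[m]
            smax = max(2.5 * ring_r[m], ring_r[m] + 2.0)
            theta, prof = _section_profile(localizer, c, e1[m], e2[m], step, smax)
            prof = np.clip(prof, 0.3 * r_med, 2.5 * r_med)
            # circular smoothing: suppress lattice-aliasing wiggles (high
            # angular harmonics) while keeping the ellipticity harmonic
            prof = ndimage.gaussian_filter1d(prof, sigma=2.0, mode="wrap")

            def r_of_theta(a, theta=theta, prof=prof):
                a = np.mod(a, 2 * math.pi)
                return np.interp(a, theta, prof, period=2 * math.pi)

            rho0 = corr * r_of_theta(ang)
            rho = _fit_ring_radii(r_of_theta, rho0, params.degree_p)
        else:
            rho = corr * np.full(N_COLS, ring_r[m])
        spokes.append(rho)
        frames.append(dirs)
    if localizer is not None and image is not None and rings >= 3:
        # end faces contaminate the wall localization of the first/last ring;
        # borrow the neighbor ring's control radii there
        spokes[0] = spokes[1]
        spokes[-1] = spokes[-2]
    for m in range(rings):
        control[m] = centers[m][None, :] + spokes[m][:, None] * frames[m]
    return BranchSurface(branch_id=branch.id, control=control, centers=centers,
                         degree_p=params.degree_p, degree_q=params.degree_q)


@dataclass
class FitSystem:
    """Assembled discrete operators of the gradient flow for one branch."""

    mass: np.ndarray  # (n_dof, n_dof) Gram matrix of the basis (rate potential)
    stiffness: np.ndarray  # alpha*(first-derivative Gram) + beta*(second-derivative Gram)
    quad: list  # per patch: dict(weights, R, gmap)
    n_dof: int
    force_field: ForceField | None = None
    density: ScalarField | None = None

    def force(self, control_flat: np.ndarray, lam: float) -> np.ndarray:
        """Image force vector lambda/2 * int R_I grad(|grad I_sigma|^2)(S)."""
        F = np.zeros((self.n_dof, 3))
        if self.force_field is None:
            return F
        for q in self.quad:
            S = q["R"] @ control_flat[q["gmap"]]
            f = self.force_field.interp(S)
            np.add.at(F, q["gmap"], q["R"].T @ (q["weights"][:, None] * f))
        return 0.5 * lam * F

    def energy(self, control_flat: np.ndarray, lam: float) -> float:
        """Discrete Snakes energy at the current control configuration."""
        e = 0.0
        for c in range(3):
            b = control_flat[:, c]
            e += 0.5 * float(b @ self.stiffness @ b)
        if self.density is not None:
            for q in self.quad:
                S = q["R"] @ control_flat[q["gmap"]]
                e -= 0.5 * lam * float(q["weights"] @ self.density.interp(S))
        return e


def assemble(surface: BranchSurface, force_field: ForceField | None, params: SigaParams,
             density: ScalarField | None = None) -> FitSystem:
    """Assemble mass/stiffness Gram operators and the quadrature caches.

    All integrals are over the parametric domain (the rate potential and the
    regularization of the energy are defined there), so mass and stiffness are
    configuration-independent; only the image force depends on the current
    surface.  Seam columns shared by the two patches are assembled once into
    the same global unknowns.
    """
    n_dof = surface.n_rings * N_COLS
    M = np.zeros((n_dof, n_dof))
    K = np.zeros((n_dof, n_dof))
    quad = []
    for patch, gmap in zip(surface.patches(), surface.dof_maps()):
        rule = gauss_legendre(patch, params.quad_order)
        bm = patch.basis_matrix(rule.points[:, 0], rule.points[:, 1], nderiv=2)
        w = rule.weights
        R = bm["R"]
        # nondimensionalize: derivatives per unit template arc length, so the
        # regularization weights act on shape distortion, not absolute size
        d = patch.evaluate(rule.points[:, 0], rule.points[:, 1], nderiv=1)
        c_xi = max(float(np.mean(np.linalg.norm(d["S_xi"], axis=1))), 1e-9)
        c_eta = max(float(np.mean(np.linalg.norm(d["S_eta"], axis=1))), 1e-9)
        Mloc = R.T @ (w[:, None] * R)
        K1 = (
            bm["R_xi"].T @ (w[:, None] * bm["R_xi"]) / c_xi**2
            + bm["R_eta"].T @ (w[:, None] * bm["R_eta"]) / c_eta**2
        )
        K2 = (
            bm["R_xixi"].T @ (w[:, None] * bm["R_xixi"]) / c_xi**4
            + bm["R_xieta"].T @ (w[:, None] * bm["R_xieta"]) / (c_xi**2 * c_eta**2)
            + bm["R_etaeta"].T @ (w[:, None] * bm["R_etaeta"]) / c_eta**4
        )
        ix = np.ix_(gmap, gmap)
        M[ix] += Mloc
        K[ix] += params.alpha * K1 + params.beta * K2
        quad.append({"weights": w, "R": R, "gmap": gmap})
    return FitSystem(mass=M, stiffness=K, quad=quad, n_dof=n_dof,
                     force_field=force_field, density=density)


def evolve(
    surface: BranchSurface,
    force_field: ForceField | None,
    params: SigaParams,
    density: ScalarField | None = None,
):
    """Run the semi-implicit gradient flow; returns (fitted surface, info).

    Each step solves (M/dt + K) b+ = (M/dt) b + F(b) for the three coordinate
    blocks (same SPD matrix).  Stops at ``max_iters`` or when the largest
    control-point displacement drops below ``tol`` mm.  Aborts if the energy
    rises for five consecutive steps.
    """
    system = assemble(surface, force_field, params, density=density)
    A = system.mass / params.dt + system.stiffness
    try:
        chol = cho_factor(A)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"singular evolution system for branch {surface.branch_id}") from exc
    out = surface.copy()
    b = out.control.reshape(system.n_dof, 3).copy()
    energies = [system.energy(b, params.lam)]
    n_bad = 0
    iters = 0
    for iters in range(1, params.max_iters + 1):
        rhs = (system.mass / params.dt) @ b + system.force(b, params.lam)
        b_new = cho_solve(chol, rhs)
        disp = float(np.max(np.linalg.norm(b_new - b, axis=1)))
        b = b_new
        energies.append(system.energy(b, params.lam))
        if energies[-1] > energies[-2] + 1e-6 * max(1.0, abs(energies[-2])):
            n_bad += 1
            if n_bad >= 5:
                raise RuntimeError(
                    f"energy diverged for branch {surface.branch_id}: "
                    f"last energies {energies[-6:]}"
                )
        else:
            n_bad = 0
        if disp < params.tol:
            break
    out.control = b.reshape(out.n_rings, N_COLS, 3)
    return out, {"energies": energies, "iterations": iters, "system": system}


# ------------------------------------------------------------- voxelization

def _mesh_to_mask(vertices: np.ndarray, faces: np.ndarray, template: BinaryImage) -> np.ndarray:
    """Scanline parity voxelization: a voxel is inside iff a +k ray from its
    center crosses the triangle mesh an odd number of times below it."""
    V = template.world_to_voxel(vertices)
    V = V + np.array([1e-4, 2e-4, 0.0])  # dodge rays through triangle edges
    shape = template.shape
    crossings: dict = {}
    for f in faces:
        A, B, C = V[f[0]], V[f[1]], V[f[2]]
        det = (B[0] - A[0]) * (C[1] - A[1]) - (B[1] - A[1]) * (C[0] - A[0])
        if abs(det) < 1e-12:
            continue
        i0 = max(0, int(math.ceil(min(A[0], B[0], C[0]))))
        i1 = min(shape[0] - 1, int(math.floor(max(A[0], B[0], C[0]))))
        j0 = max(0, int(math.ceil(min(A[1], B[1], C[1]))))
        j1 = min(shape[1] - 1, int(math.floor(max(A[1], B[1], C[1]))))
        if i1 < i0 or j1 < j0:
            continue
        ii, jj = np.meshgrid(np.arange(i0, i1 + 1), np.arange(j0, j1 + 1), indexing="ij")
        px = ii.ravel().astype(float)
        py = jj.ravel().astype(float)
        u = ((px - A[0]) * (C[1] - A[1]) - (py - A[1]) * (C[0] - A[0])) / det
        v = ((B[0] - A[0]) * (py - A[1]) - (B[1] - A[1]) * (px - A[0])) / det
        hit = (u >= 0) & (v >= 0) & (u + v <= 1)
        if not np.any(hit):
            continue
        z = A[2] + u[hit] * (B[2] - A[2]) + v[hit] * (C[2] - A[2])
        for i, j, zz in zip(ii.ravel()[hit], jj.ravel()[hit], z):
            crossings.setdefault((int(i), int(j)), []).append(float(zz))
    mask = np.zeros(shape, dtype=np.uint8)
    for (i, j), zs in crossings.items():
        zs.sort()
        for a in range(0, len(zs) - 1, 2):
            k0 = max(0, int(math.ceil(zs[a])))
            k1 = min(shape[2] - 1, int(math.floor(zs[a + 1])))
            if k1 >= k0:
                mask[i, j, k0 : k1 + 1] = 1
    return mask


def voxelize(closed_surfaces, template: BinaryImage, tess_factor: int = 8) -> BinaryImage:
    """Rasterize closed branch surfaces onto the template lattice (I_siga).

    A voxel is 1 iff its center lies inside any closed branch surface; the
    result is the union over branches.  Surfaces must be capped (watertight).
    """
    from .morphometry import ClosedBranchSurface, tessellate_closed  # lazy: avoid cycle

    data = np.zeros(template.shape, dtype=np.uint8)
    surfaces = list(closed_surfaces)
    if any(not isinstance(s, ClosedBranchSurface) for s in surfaces):
        raise TypeError("voxelize needs capped ClosedBranchSurface objects (see morphometry.cap_surface)")
    for s in surfaces:
        V, F = tessellate_closed(s, factor=tess_factor)
        data |= _mesh_to_mask(V, F, template)
    return BinaryImage(data=data, spacing=template.spacing, affine=template.affine)


def dice(a: BinaryImage, b: BinaryImage) -> float:
    """DICE overlap 2|A∩B| / (|A|+|B|) between two same-lattice masks.

    1 means identical nonempty masks, 0 disjoint; 0.7 is the conventional
    acceptability threshold for segmentation agreement.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.data.sum()), int(b.data.sum())
    if na + nb == 0:
        raise ValueError("DICE undefined: both masks are empty")
    inter = int(np.sum((a.data > 0) & (b.data > 0)))
    return 2.0 * inter / (na + nb)


@dataclass
class FitResult:
    """Full-pipeline output: branch graph, fitted and capped surfaces, I_siga, DICE."""

    graph: BranchGraph
    surfaces: dict  # branch id -> BranchSurface
    closed: dict  # branch id -> ClosedBranchSurface
    i_siga: BinaryImage
    dice: float
    traces: dict  # branch id -> energy list


def fit_mask(
    img: BinaryImage,
    params: SigaParams | None = None,
    skeleton: Skeleton | None = None,
    root_hint=None,
    merge_threshold: float = 0.3,
) -> FitResult:
    """End-to-end SIGA fit of a binary airway mask.

    Smooths the mask (sigma voxels), computes the edge force field, extracts
    (or accepts) the centerline, builds the branch graph with short-branch
    trifurcation merging, fits each branch independently, caps the mantles,
    voxelizes the union and reports the DICE against the input mask.
    """
    from . import morphometry  # lazy: morphometry imports this module

    params = params or SigaParams()
    smoothed = gaussian_smooth(img, params.sigma)
    density = edge_density(smoothed)
    force_field = image_force(smoothed)
    localizer = gaussian_smooth(img, LOCALIZER_SIGMA)

    if skeleton is None:
        skeleton = skeletonize(img)
    graph = build_branch_graph(skeleton, root_hint=root_hint)
    graph = merge_short_branches(graph, merge_threshold)

    surfaces, closed, traces = {}, {}, {}
    for branch in graph:
        init = build_templates(branch, image=img, localizer=localizer, params=params)
        fitted, info = evolve(init, force_field, params, density=density)
        surfaces[branch.id] = fitted
        closed[branch.id] = morphometry.cap_surface(fitted)
        traces[branch.id] = info["energies"]
    i_siga = voxelize(closed.values(), img)
    d = dice(img, i_siga)
    return FitResult(graph=graph, surfaces=surfaces, closed=closed, i_siga=i_siga, dice=d, traces=traces)
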