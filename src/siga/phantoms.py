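"""Synthetic tubular phantoms with analytic ground truth.

Airway-like binary masks (straight, elliptic and bent tubes, Y bifurcations,
dichotomous trees, short-branch forks) are rasterized on an anisotropic voxel
lattice mirroring the CT geometry (default spacing 0.7 x 0.7 x 0.5 mm).  Each
phantom carries closed-form volume/area/eccentricity/length, its analytic
centerline, and the expected airway counts, so every pipeline stage can be
validated without patient data.  Tubes narrower than 3 voxels in diameter are
refused, mirroring the segmentability floor of the imaging protocol.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import BinaryImage
from .skeleton import Skeleton

__all__ = ["PhantomSpec", "GroundTruth", "GroundTruthBranch", "generate", "jitter_boundary"]

_KINDS = ("cylinder", "elliptic_cylinder", "bent_tube", "y_bifurcation", "dichotomous_tree", "short_branch")


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom; the seed fixes the output exactly."""

    kind: str = "cylinder"
    radius: float = 3.0  # mm (tube radius; root radius for trees)
    semi_axes: tuple = (2.0, 4.0)  # mm, elliptic cross-section
    length: float = 20.0  # mm (arc length for bent tubes; root length for trees)
    bend_angle: float = 60.0  # degrees, bent tube
    branch_angle: float = 35.0  # degrees from parent direction at bifurcations
    generations: int = 2  # tree depth (deepest generation index)
    radius_decay: float = 0.8  # per-generation radius factor
    length_decay: float = 0.75  # per-generation length factor
    pc_target: float = 0.15  # length/radius ratio of the short branch phantom
    spacing: tuple = (0.7, 0.7, 0.5)  # mm
    noise: float = 0.0  # boundary jitter amplitude, voxels
    seed: int = 0
    margin: float = 3.0  # mm of background padding around the solid

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {_KINDS}")
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("lengths and radii must be positive")


@dataclass
class GroundTruthBranch:
    axis: np.ndarray  # (N, 3) analytic centerline, mm
    radius: float  # tube radius (minor semi-axis for elliptic), mm
    generation: int
    parent: int | None
    length: float  # mm
    volume: float  # mm^3
    lateral_area: float  # mm^2
    eccen: float


@dataclass
class GroundTruth:
    branches: list
    volume: float  # total solid volume, mm^3 (overlap at junctions not double counted analytically for single tubes)
    expected_tac: int
    expected_gac: dict


# ---------------------------------------------------------------- primitives

def _inside_cylinder(P, p0, p1, r):
    d = p1 - p0
    L2 = float(d @ d)
    t = ((P - p0) @ d) / L2
    foot = p0[None, :] + t[:, None] * d[None, :]
    rad2 = np.sum((P - foot) ** 2, axis=1)
    return (t >= 0) & (t <= 1) & (rad2 <= r * r)


def _inside_elliptic(P, p0, p1, a, b, e1, e2):
    d = p1 - p0
    L2 = float(d @ d)
    t = ((P - p0) @ d) / L2
    rel = P - (p0[None, :] + t[:, None] * d[None, :])
    u = rel @ e1
    v = rel @ e2
    return (t >= 0) & (t <= 1) & ((u / a) ** 2 + (v / b) ** 2 <= 1.0)


def _inside_arc_tube(P, center, R_arc, r, e1, e2, theta):
    w = P - center
    n = np.cross(e1, e2)
    w1, w2, w3 = w @ e1, w @ e2, w @ n
    phi = np.arctan2(w2, w1)
    rho = np.hypot(w1, w2)
    d2 = (rho - R_arc) ** 2 + w3 ** 2
    return (phi >= 0) & (phi <= theta) & (d2 <= r * r)


# ----------------------------------------------------------------- assembly

def _tree_layout(spec: PhantomSpec):
    """Recursive dichotomous layout: list of (p0, p1, radius, generation, parent)."""
    segs = []

    def recurse(p0, direction, gen, parent):
        L = spec.length * spec.length_decay ** gen
        r = spec.radius * spec.radius_decay ** gen
        p1 = p0 + L * direction
        idx = len(segs)
        segs.append((p0, p1, r, gen, parent))
        if gen < spec.generations:
            phi = math.radians(spec.branch_angle)
            # branching plane alternates with depth to limit collisions
            up = np.array([1.0, 0, 0]) if gen % 2 == 0 else np.array([0, 1.0, 0])
            side = np.cross(direction, up)
            if np.linalg.norm(side) < 1e-9:
                side = np.cross(direction, np.array([0, 0, 1.0]))
            side /= np.linalg.norm(side)
            for sgn in (+1, -1):
                d = math.cos(phi) * direction + sgn * math.sin(phi) * side
                d /= np.linalg.norm(d)
                recurse(p1, d, gen + 1, idx)

    recurse(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0, None)
    return segs


def _axis_nodes(p0, p1, step=1.0):
    L = float(np.linalg.norm(p1 - p0))
    n = max(2, int(round(L / step)) + 1)
    t = np.linspace(0.0, 1.0, n)
    return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


def _check_floor(spec, diameters_mm):
    floor = 3.0 * min(spec.spacing[0], spec.spacing[1])
    dmin = min(diameters_mm)
    if dmin < floor:
        raise ValueError(
            f"tube diameter {dmin:.2f} mm is below the segmentability floor of "
            f"3 voxels ({floor:.2f} mm); refuse to rasterize"
        )


def generate(spec: PhantomSpec):
    """Rasterize a phantom; returns ``(BinaryImage, GroundTruth, Skeleton)``.

    A voxel is foreground iff its center lies inside the analytic solid
    (before any jitter).  The reference skeleton is the analytic axis sampled
    at roughly 1 mm intervals with exact tube radii; for trees, junction nodes
    are shared between parent and children.
    """
    sp = np.asarray(spec.spacing, dtype=float)
    cyls = []       # (p0, p1, r) circular tubes
    gt_branches = []
    ell = None
    arc = None

    if spec.kind == "cylinder":
        _check_floor(spec, [2 * spec.radius])
        p0, p1 = np.zeros(3), np.array([0, 0, spec.length])
        cyls.append((p0, p1, spec.radius))
        gt_branches.append(
            GroundTruthBranch(
                axis=_axis_nodes(p0, p1), radius=spec.radius, generation=0, parent=None,
                length=spec.length, volume=math.pi * spec.radius ** 2 * spec.length,
                lateral_area=2 * math.pi * spec.radius * spec.length, eccen=0.0,
            )
        )
    elif spec.kind == "elliptic_cylinder":
        a, b = max(spec.semi_axes), min(spec.semi_axes)
        _check_floor(spec, [2 * b])
        p0, p1 = np.zeros(3), np.array([0, 0, spec.length])
        e1, e2 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        ell = (p0, p1, max(spec.semi_axes), min(spec.semi_axes), e1, e2)
        gt_branches.append(
            GroundTruthBranch(
                axis=_axis_nodes(p0, p1), radius=b, generation=0, parent=None,
                length=spec.length, volume=math.pi * a * b * spec.length,
                lateral_area=_ellipse_perimeter(a, b) * spec.length,
                eccen=math.sqrt(1 - (b / a) ** 2),
            )
        )
    elif spec.kind == "bent_tube":
        _check_floor(spec, [2 * spec.radius])
        theta = math.radians(spec.bend_angle)
        R_arc = spec.length / theta
        if R_arc <= spec.radius:
            raise ValueError("bend too tight: arc radius must exceed tube radius")
        center = np.array([R_arc, 0.0, 0.0])
        e1, e2 = np.array([-1.0, 0, 0]), np.array([0.0, 0, 1.0])  # arc starts at origin heading +z
        arc = (center, R_arc, spec.radius, e1, e2, theta)
        tt = np.linspace(0, theta, max(2, int(spec.length) + 1))
        axis = center[None, :] + R_arc * (np.outer(np.cos(tt), e1) + np.outer(np.sin(tt), e2))
        gt_branches.append(
            GroundTruthBranch(
                axis=axis, radius=spec.radius, generation=0, parent=None,
                length=spec.length, volume=math.pi * spec.radius ** 2 * spec.length,
                lateral_area=2 * math.pi * spec.radius * spec.length, eccen=0.0,
            )
        )
    elif spec.kind == "y_bifurcation":
        r0, r1 = spec.radius, spec.radius * spec.radius_decay
        _check_floor(spec, [2 * r1])
        phi = math.radians(spec.branch_angle)
        p0, p1 = np.zeros(3), np.array([0, 0, spec.length])
        Lc = spec.length * spec.length_decay
        segs = [(p0, p1, r0, 0, None)]
        for sgn in (+1, -1):
            d = np.array([sgn * math.sin(phi), 0.0, math.cos(phi)])
            segs.append((p1, p1 + Lc * d, r1, 1, 0))
        for s0, s1, r, g, par in segs:
            cyls.append((s0, s1, r))
            gt_branches.append(
                GroundTruthBranch(
                    axis=_axis_nodes(s0, s1), radius=r, generation=g, parent=par,
                    length=float(np.linalg.norm(s1 - s0)), volume=math.pi * r ** 2 * float(np.linalg.norm(s1 - s0)),
                    lateral_area=2 * math.pi * r * float(np.linalg.norm(s1 - s0)), eccen=0.0,
                )
            )
    elif spec.kind == "dichotomous_tree":
        r_leaf = spec.radius * spec.radius_decay ** spec.generations
        _check_floor(spec, [2 * r_leaf])
        for s0, s1, r, g, par in _tree_layout(spec):
            cyls.append((s0, s1, r))
            L = float(np.linalg.norm(s1 - s0))
            gt_branches.append(
                GroundTruthBranch(
                    axis=_axis_nodes(s0, s1), radius=r, generation=g, parent=par, length=L,
                    volume=math.pi * r ** 2 * L, lateral_area=2 * math.pi * r * L, eccen=0.0,
                )
            )
    elif spec.kind == "short_branch":
        # parent -> {normal child, short child -> 2 grandchildren}; the short
        # child has length pc_target * radius, below the 0.3 merge threshold.
        r0 = spec.radius
        _check_floor(spec, [2 * r0 * spec.radius_decay ** 2])
        phi = math.radians(spec.branch_angle)
        p0, p1 = np.zeros(3), np.array([0, 0, spec.length])
        rc = r0 * spec.radius_decay
        Lc = spec.length * spec.length_decay
        d_norm = np.array([math.sin(phi), 0.0, math.cos(phi)])
        d_short = np.array([-math.sin(phi), 0.0, math.cos(phi)])
        L_short = spec.pc_target * rc
        p_short = p1 + L_short * d_short
        rg = r0 * spec.radius_decay ** 2
        Lg = Lc * spec.length_decay
        segs = [
            (p0, p1, r0, 0, None),
            (p1, p1 + Lc * d_norm, rc, 1, 0),
            (p1, p_short, rc, 1, 0),
        ]
        for sgn in (+1, -1):
            d = np.array([-math.sin(phi + sgn * phi / 2), 0.0, math.cos(phi + sgn * phi / 2)])
            segs.append((p_short, p_short + Lg * d, rg, 2, 2))
        for s0, s1, r, g, par in segs:
            cyls.append((s0, s1, r))
            L = float(np.linalg.norm(s1 - s0))
            gt_branches.append(
                GroundTruthBranch(
                    axis=_axis_nodes(s0, s1, step=min(0.5, L / 2)), radius=r, generation=g,
                    parent=par, length=L, volume=math.pi * r ** 2 * L,
                    lateral_area=2 * math.pi * r * L, eccen=0.0,
                )
            )

    # lattice: bounding box of all primitives plus margin
    pts = np.concatenate([b.axis for b in gt_branches])
    rmax = max(max(b.radius for b in gt_branches), max(spec.semi_axes) if ell else 0.0)
    lo = pts.min(axis=0) - rmax - spec.margin
    hi = pts.max(axis=0) + rmax + spec.margin
    # sub-voxel shift so voxel centers never sit exactly on the analytic
    # surface (on-surface ties would bias the rasterized volume)
    lo = lo - 0.37 * sp
    shape = tuple(int(math.ceil((hi[a] - lo[a]) / sp[a])) + 1 for a in range(3))
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = sp
    affine[:3, 3] = lo

    II, JJ, KK = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    centers = np.stack([II, JJ, KK], axis=-1).reshape(-1, 3) * sp[None, :] + lo[None, :]
    inside = np.zeros(centers.shape[0], dtype=bool)
    for p0, p1, r in cyls:
        inside |= _inside_cylinder(centers, np.asarray(p0, float), np.asarray(p1, float), r)
    if ell is not None:
        inside |= _inside_elliptic(centers, *ell)
    if arc is not None:
        inside |= _inside_arc_tube(centers, *arc)
    data = inside.reshape(shape).astype(np.uint8)

    img = BinaryImage(data=data, spacing=tuple(sp), affine=affine)
    if spec.noise > 0:
        img = jitter_boundary(img, spec.noise, spec.seed)

    gac = {}
    for b in gt_branches:
        gac[b.generation] = gac.get(b.generation, 0) + 1
    gt = GroundTruth(
        branches=gt_branches,
        volume=sum(b.volume for b in gt_branches),
        expected_tac=len(gt_branches),
        expected_gac=gac,
    )
    skel = _reference_skeleton(gt_branches)
    return img, gt, skel


def _ellipse_perimeter(a, b):
    """Ramanujan's second approximation (relative error < 1e-6 for a/b <= 4)."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def _reference_skeleton(branches) -> Skeleton:
    nodes, radii, edges = [], [], []
    index = {}

    def key(p):
        return tuple(np.round(p, 6))

    for b in branches:
        prev = None
        for p in b.axis:
            k = key(p)
            if k in index:
                idx = index[k]
            else:
                idx = len(nodes)
                nodes.append(np.asarray(p, float))
                radii.append(b.radius)
                index[k] = idx
            if prev is not None and prev != idx:
                edges.append((prev, idx))
            prev = idx
    return Skeleton(nodes=np.asarray(nodes), radii=np.asarray(radii), edges=edges)


def jitter_boundary(img: BinaryImage, amplitude: float, seed: int = 0) -> BinaryImage:
    """Flip a random subset of voxels within ``amplitude`` voxels of the boundary.

    The boundary surface is taken halfway between foreground and background
    voxel centers, so the first shell on either side sits at distance 0.5
    voxels and is already inside the band for amplitude 0.5.  Flip probability
    decays linearly from 0.5 at the boundary to 0 beyond the band, emulating
    partial-volume indecision at the lumen wall.  Amplitude 0 is the identity;
    the seed fixes the output.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return img
    d_in = ndimage.distance_transform_edt(img.data)
    d_out = ndimage.distance_transform_edt(1 - img.data)
    dist = np.where(img.data > 0, d_in, d_out) - 0.5
    band = dist <= amplitude
    rng = np.random.default_rng(seed)
    p = 0.25 * np.clip(1.0 - dist / (amplitude + 0.5), 0.0, 1.0)
    flips = band & (rng.random(img.data.shape) < p)
    data = img.data.copy()
    data[flips] ^= 1
    return BinaryImage(data=data, spacing=img.spacing, affine=img.affine)
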