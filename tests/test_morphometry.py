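import math

import numpy as np
import pytest

from siga import fit as fitmod
from siga import morphometry as mm
from siga import phantoms
from siga.skeleton import Branch, build_branch_graph, merge_short_branches, skeletonize

CYL_VOL = math.pi * 9 * 20  # r=3, L=20
CYL_MANTLE = 2 * math.pi * 3 * 20
CYL_CAPS = 2 * math.pi * 9


@pytest.fixture(scope="module")
def capped_cylinder(cylinder_template):
    return mm.cap_surface(cylinder_template)


def template_from_phantom(phantom):
    """Template surface measured on the (clean) phantom mask, reference skeleton."""
    img, gt, ref = phantom
    graph = build_branch_graph(ref)
    branch = max(graph, key=lambda b: b.length)
    surf = fitmod.build_templates(branch, image=img, params=fitmod.SigaParams())
    return img, gt, branch, surf


# ---------------------------------------------------------------- capping

def test_caps_are_watertight(capped_cylinder):
    V, F = mm.tessellate_closed(capped_cylinder, factor=4)
    edges = set()
    for f in F:
        for i in range(3):
            edges.add(tuple(sorted((f[i], f[(i + 1) % 3]))))
    assert len(V) - len(edges) + len(F) == 2  # Euler characteristic of a sphere


def test_cap_rim_coincides_with_mantle_boundary(capped_cylinder):
    mantle_p1, mantle_p2 = capped_cylinder.mantle.patches()
    u = np.linspace(0, 1, 33)
    rim_mantle = np.concatenate(
        [mantle_p1.evaluate(u, np.zeros_like(u))["S"], mantle_p2.evaluate(u, np.zeros_like(u))["S"]]
    )
    rim_cap = np.concatenate([p.evaluate(u, np.zeros_like(u))["S"] for p in capped_cylinder.inlet])
    # same point sets up to ordering
    from scipy.spatial import cKDTree

    d, _ = cKDTree(rim_cap).query(rim_mantle)
    assert d.max() < 1e-9


def test_cap_outward_orientation_positive_volume(capped_cylinder):
    assert mm.lumen_volume(capped_cylinder) > 0


def test_cap_area_close_to_disc(capped_cylinder):
    total = mm.surface_area(capped_cylinder, include_caps=True)
    mantle = mm.surface_area(capped_cylinder, include_caps=False)
    cap_area = (total - mantle) / 2.0
    assert cap_area == pytest.approx(math.pi * 9, rel=0.05)  # 28.27 mm^2 per end


def test_cap_degenerate_ring_rejected(cylinder_template):
    broken = cylinder_template.copy()
    broken.control[0] = broken.centers[0]
    with pytest.raises(ValueError, match="degenerate"):
        mm.cap_surface(broken)


# ----------------------------------------------------------------- volume

def test_cylinder_volume_closed_form(capped_cylinder):
    assert mm.lumen_volume(capped_cylinder) == pytest.approx(CYL_VOL, rel=0.02)


def test_volume_translation_invariance(cylinder_template):
    base = mm.lumen_volume(mm.cap_surface(cylinder_template))
    moved = cylinder_template.copy()
    moved.control += np.array([100.0, -50.0, 7.0])
    moved.centers += np.array([100.0, -50.0, 7.0])
    shifted = mm.lumen_volume(mm.cap_surface(moved))
    assert abs(shifted - base) / base < 1e-8


def test_volume_rigid_motion_invariance(cylinder_template):
    base_closed = mm.cap_surface(cylinder_template)
    base_v = mm.lumen_volume(base_closed)
    base_a = mm.surface_area(base_closed)
    theta = 0.9
    R = np.array([[1, 0, 0], [0, np.cos(theta), -np.sin(theta)], [0, np.sin(theta), np.cos(theta)]])
    moved = cylinder_template.copy()
    moved.control = moved.control @ R.T + np.array([3.0, 4.0, -5.0])
    moved.centers = moved.centers @ R.T + np.array([3.0, 4.0, -5.0])
    closed = mm.cap_surface(moved)
    assert abs(mm.lumen_volume(closed) - base_v) / base_v < 1e-8
    assert abs(mm.surface_area(closed) - base_a) / base_a < 1e-8


@pytest.mark.parametrize("kind", ["cylinder", "elliptic_cylinder", "bent_tube"])
def test_volume_against_closed_form_and_voxel_oracle(kind):
    # half spacing keeps voxel-oracle aliasing well below the 5% bar
    phantom = phantoms.generate(phantoms.PhantomSpec(kind=kind, spacing=(0.35, 0.35, 0.25)))
    img, gt, branch, surf = template_from_phantom(phantom)
    vol = mm.lumen_volume(mm.cap_surface(surf))
    assert vol == pytest.approx(gt.volume, rel=0.05)
    voxel_vol = img.data.sum() * img.voxel_volume
    assert vol == pytest.approx(voxel_vol, rel=0.05)


def test_volume_negative_orientation_repaired(cylinder_template):
    closed = mm.cap_surface(cylinder_template)
    inverted = mm.ClosedBranchSurface(
        mantle=mm._flip_mantle(closed.mantle),
        inlet=[mm._flip_patch(p) for p in closed.outlet],
        outlet=[mm._flip_patch(p) for p in closed.inlet],
    )
    assert mm._signed_volume(inverted) < 0
    v = mm.lumen_volume(inverted)  # one flip repairs it
    assert v == pytest.approx(CYL_VOL, rel=0.02)


# ------------------------------------------------------------------- area

def test_mantle_area_closed_form(capped_cylinder):
    assert mm.surface_area(capped_cylinder, include_caps=False) == pytest.approx(CYL_MANTLE, rel=0.02)


def test_full_area_closed_form(capped_cylinder):
    assert mm.surface_area(capped_cylinder, include_caps=True) == pytest.approx(
        CYL_MANTLE + CYL_CAPS, rel=0.02
    )


def test_degenerate_flat_patch_zero_area():
    from siga.nurbs import NurbsPatch, open_uniform_knots, patch_area

    ctrl = np.zeros((4, 4, 3))  # all control points coincide
    patch = NurbsPatch(3, 3, open_uniform_knots(4, 3), open_uniform_knots(4, 3), ctrl)
    assert patch_area(patch) == pytest.approx(0.0, abs=1e-12)


# ------------------------------------------------------------------- SA:V

def test_sa_v_cylinder_closed_form(capped_cylinder):
    vol = mm.lumen_volume(capped_cylinder)
    area = mm.surface_area(capped_cylinder)
    assert mm.sa_v(area, vol) == pytest.approx(2.0 / 3.0 + 2.0 / 20.0, rel=0.02)


def test_sa_v_monotone_in_radius():
    def ratio(r):
        z = np.linspace(0, 20, 15)
        br = Branch(id=0, nodes=np.column_stack([0 * z, 0 * z, z]), radii=np.full(len(z), r))
        closed = mm.cap_surface(fitmod.build_templates(br))
        return mm.sa_v(mm.surface_area(closed), mm.lumen_volume(closed))

    assert ratio(1.5) > ratio(3.0)


def test_sa_v_arithmetic_and_errors():
    assert mm.sa_v(10.0, 5.0) == 2.0
    with pytest.raises(ValueError):
        mm.sa_v(10.0, 0.0)


def test_sa_v_increases_generation_by_generation():
    """Radii shrink by a fixed factor per generation, so SA:V must climb."""
    _, _, ref = phantoms.generate(
        phantoms.PhantomSpec(kind="dichotomous_tree", generations=2, radius=3.0, length=18.0)
    )
    graph = build_branch_graph(ref)
    surfaces = {b.id: fitmod.build_templates(b) for b in graph}
    df = mm.measure_tree(surfaces, graph)
    means = df.groupby("generation")["sa_v_mm-1"].mean()
    assert means[0] < means[1] < means[2]


# ------------------------------------------------------------------ radii

def test_radii_circular_cylinder(cylinder_template, straight_branch):
    r_min, r_avg, r_max = mm.radii(cylinder_template, straight_branch)
    assert r_min <= r_avg <= r_max
    for r in (r_min, r_avg, r_max):
        assert r == pytest.approx(3.0, abs=0.15)


def test_radii_elliptic_cylinder(elliptic_phantom):
    img, gt, branch, surf = template_from_phantom(elliptic_phantom)
    r_min, r_avg, r_max = mm.radii(surf, branch)
    assert r_min == pytest.approx(2.0, rel=0.05)
    assert r_max == pytest.approx(4.0, rel=0.05)


def test_radii_against_dense_sampling_oracle(cylinder_template, straight_branch):
    """Independent dense-sample nearest-segment oracle within 2%."""
    r_min, r_avg, r_max = mm.radii(cylinder_template, straight_branch)
    rng = np.random.default_rng(12)
    pts = []
    for patch in cylinder_template.patches():
        u = rng.uniform(0, 1, 5000)
        v = rng.uniform(0, 1, 5000)
        pts.append(patch.evaluate(u, v)["S"])
    P = np.concatenate(pts)
    nodes = straight_branch.nodes
    a, d = nodes[:-1], np.diff(nodes, axis=0)
    L2 = np.sum(d * d, axis=1)
    t = np.einsum("pnc,nc->pn", P[:, None, :] - a[None], d) / L2[None]
    foot = a[None] + t[..., None] * d[None]
    dist = np.linalg.norm(P[:, None] - foot, axis=2)
    dist = np.where((t >= 0) & (t <= 1), dist, np.inf)
    seg = np.argmin(dist, axis=1)
    best = dist[np.arange(len(P)), seg]
    ok = np.isfinite(best)
    mins = [best[ok & (seg == s)].min() for s in range(len(a)) if np.any(ok & (seg == s))]
    maxs = [best[ok & (seg == s)].max() for s in range(len(a)) if np.any(ok & (seg == s))]
    assert r_min == pytest.approx(np.mean(mins), rel=0.02)
    assert r_max == pytest.approx(np.mean(maxs), rel=0.02)


# ------------------------------------------------------------ eccentricity

def test_eccentricity_circle_is_zero():
    assert mm.eccentricity(3.0, 3.0) == 0.0


def test_eccentricity_two_to_one_ratio():
    assert mm.eccentricity(1.0, 2.0) == pytest.approx(math.sqrt(3) / 2)


def test_eccentricity_monotone_in_axis_ratio():
    vals = [mm.eccentricity(1.0, ratio) for ratio in (1.0, 1.5, 2.0, 3.0)]
    assert vals[0] == 0.0
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_eccentricity_rejects_bad_arguments():
    with pytest.raises(ValueError):
        mm.eccentricity(3.0, 2.0)
    with pytest.raises(ValueError):
        mm.eccentricity(0.0, 2.0)


def test_elliptic_pipeline_recovers_eccentricity(elliptic_phantom):
    img, _, _ = elliptic_phantom
    res = fitmod.fit_mask(img)
    branch = max(res.graph, key=lambda b: b.length)
    r_min, _, r_max = mm.radii(res.surfaces[branch.id], branch)
    assert mm.eccentricity(r_min, r_max) == pytest.approx(math.sqrt(3) / 2, abs=0.05)


# ------------------------------------------------------------ measure_tree

def test_measure_tree_single_tube(clean_cylinder, cylinder_template, straight_branch):
    from siga.skeleton import BranchGraph

    graph = BranchGraph(branches={0: straight_branch}, root=0)
    df = mm.measure_tree({0: cylinder_template}, graph)
    assert len(df) == 1
    row = df.iloc[0]
    assert row["sa_v_mm-1"] == pytest.approx(row["area_mm2"] / row["volume_mm3"])
    assert np.isfinite(
        row[["volume_mm3", "area_mm2", "r_min_mm", "r_max_mm", "eccen", "length_mm"]].astype(float)
    ).all()
    assert row["tac"] == 1 and row["gac"] == 1


def test_measure_tree_y_phantom(y_phantom):
    img, _, _ = y_phantom
    res = fitmod.fit_mask(img)
    df = mm.measure_tree(res.surfaces, res.graph)
    assert len(df) == 3
    assert sorted(df["generation"]) == [0, 1, 1]


def test_measure_tree_depth2_gac():
    _, _, ref = phantoms.generate(
        phantoms.PhantomSpec(kind="dichotomous_tree", generations=2, radius=3.0, length=18.0)
    )
    graph = build_branch_graph(ref)
    surfaces = {b.id: fitmod.build_templates(b) for b in graph}
    df = mm.measure_tree(surfaces, graph)
    gac_by_gen = df.groupby("generation")["gac"].first()
    assert list(gac_by_gen) == [1, 2, 4]


def test_measure_tree_missing_surface_flagged(straight_branch):
    from siga.skeleton import BranchGraph

    graph = BranchGraph(branches={0: straight_branch}, root=0)
    with pytest.warns(UserWarning, match="missing"):
        df = mm.measure_tree({}, graph)
    assert len(df) == 1 and bool(df.iloc[0]["missing"])
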