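import numpy as np
import pytest

from siga import fit as fitmod
from siga import morphometry, phantoms
from siga.image import BinaryImage, gaussian_smooth, image_force
from siga.nurbs import basis_derivatives, gauss_legendre
from siga.skeleton import Branch


def sampled_radius(surface, v, n=200):
    u = np.linspace(0, 1, n)
    rr = []
    for patch in surface.patches():
        pts = patch.evaluate(u, np.full_like(u, v))["S"]
        center = surface.centers[0] * (1 - v) + surface.centers[-1] * v
        rr.append(np.linalg.norm(pts[:, :2] - center[None, :2], axis=1))
    return np.concatenate(rr)


# --------------------------------------------------------------- templates

def test_template_radius_matches_branch(cylinder_template):
    for v in (0.2, 0.5, 0.8):
        r = sampled_radius(cylinder_template, v)
        assert r.mean() == pytest.approx(3.0, abs=0.05)
        assert r.min() > 3.0 - 0.15 and r.max() < 3.0 + 0.15  # octagon tolerance


def test_template_two_node_branch_degenerate_input():
    br = Branch(id=0, nodes=np.array([[0, 0, 0.0], [0, 0, 6.0]]), radii=np.array([2.0, 2.0]))
    surf = fitmod.build_templates(br)
    assert surf.n_rings >= 4  # enough rings for a cubic eta direction


def test_template_zero_radius_fallback():
    br = Branch(id=0, nodes=np.array([[0, 0, 0.0], [0, 0, 6.0]]), radii=np.zeros(2))
    with pytest.warns(UserWarning, match="zero local radius"):
        surf = fitmod.build_templates(br)
    assert np.all(np.isfinite(surf.control))


def test_frames_do_not_flip_on_bend():
    # 90-degree bend of radius 20 mm
    t = np.linspace(0, np.pi / 2, 30)
    nodes = np.column_stack([20 * (1 - np.cos(t)), np.zeros_like(t), 20 * np.sin(t)])
    br = Branch(id=0, nodes=nodes, radii=np.full(len(t), 3.0))
    surf = fitmod.build_templates(br)
    e1, e2, tt = fitmod._rotation_minimizing_frames(surf.centers)
    angles = np.degrees(np.arccos(np.clip(np.einsum("ic,ic->i", e1[:-1], e1[1:]), -1, 1)))
    assert angles.max() < 15.0


def test_octagon_correction_traces_circle():
    corr = np.asarray(fitmod._octagon_correction(3))
    assert corr.shape == (8,)
    br = Branch(id=0, nodes=np.array([[0, 0, 0.0], [0, 0, 10.0]]), radii=np.array([1.0, 1.0]))
    surf = fitmod.build_templates(br)
    r = sampled_radius(surf, 0.5)
    assert abs(r.mean() - 1.0) < 0.01
    assert r.max() - r.min() < 0.1


# ---------------------------------------------------------------- assembly

def test_assemble_zero_regularization_zero_stiffness(cylinder_template):
    params = fitmod.SigaParams(alpha=1e-30, beta=1e-30)
    system = fitmod.assemble(cylinder_template, None, params)
    assert np.abs(system.stiffness).max() < 1e-12


def test_assemble_no_force_field_gives_zero_force(cylinder_template):
    system = fitmod.assemble(cylinder_template, None, fitmod.SigaParams())
    b = cylinder_template.control.reshape(-1, 3)
    np.testing.assert_allclose(system.force(b, lam=0.1), 0.0)


def test_first_derivative_gram_matches_direct_summation(cylinder_template):
    """alpha-only stiffness vs an independent dense quadrature summation."""
    params = fitmod.SigaParams(alpha=0.7, beta=1e-30)
    system = fitmod.assemble(cylinder_template, None, params)
    surf = cylinder_template
    n_dof = surf.n_rings * fitmod.N_COLS
    K_oracle = np.zeros((n_dof, n_dof))
    for patch, gmap in zip(surf.patches(), surf.dof_maps()):
        rule = gauss_legendre(patch, 4)
        d = patch.evaluate(rule.points[:, 0], rule.points[:, 1], nderiv=1)
        c_xi = np.mean(np.linalg.norm(d["S_xi"], axis=1))
        c_eta = np.mean(np.linalg.norm(d["S_eta"], axis=1))
        nu, nv = patch.shape
        for (u, v), w in zip(rule.points, rule.weights):
            su, du = basis_derivatives(patch.knots_u, patch.degree_u, [u], 1)
            sv, dv = basis_derivatives(patch.knots_v, patch.degree_v, [v], 1)
            Nu = np.zeros((2, nu))
            Nv = np.zeros((2, nv))
            Nu[:, su[0] - patch.degree_u : su[0] + 1] = du[:2, 0]
            Nv[:, sv[0] - patch.degree_v : sv[0] + 1] = dv[:2, 0]
            r_xi = np.outer(Nu[1], Nv[0]).ravel()
            r_eta = np.outer(Nu[0], Nv[1]).ravel()
            local = w * (np.outer(r_xi, r_xi) / c_xi**2 + np.outer(r_eta, r_eta) / c_eta**2)
            K_oracle[np.ix_(gmap, gmap)] += 0.7 * local
    np.testing.assert_allclose(system.stiffness, K_oracle, atol=1e-10)


def test_mass_spd_stiffness_psd(cylinder_template):
    system = fitmod.assemble(cylinder_template, None, fitmod.SigaParams())
    assert np.linalg.eigvalsh(system.mass).min() > 0
    assert np.linalg.eigvalsh(system.stiffness).min() > -1e-10
    np.testing.assert_allclose(system.mass, system.mass.T, atol=1e-14)


# --------------------------------------------------------------- evolution

def test_energy_descent_without_image_term(straight_branch):
    rng = np.random.default_rng(0)
    params = fitmod.SigaParams(lam=1e-30)
    for _ in range(10):
        surf = fitmod.build_templates(straight_branch)
        surf.control += rng.normal(0, 0.5, surf.control.shape)
        _, info = fitmod.evolve(surf, None, params)
        e = np.asarray(info["energies"])
        assert np.all(np.diff(e) <= 1e-9 * np.maximum(1.0, np.abs(e[:-1])))


def test_pure_smoothing_contracts_perturbations(straight_branch):
    rng = np.random.default_rng(3)
    surf = fitmod.build_templates(straight_branch)
    noisy = surf.copy()
    noisy.control += rng.normal(0, 0.4, surf.control.shape)
    fitted, _ = fitmod.evolve(noisy, None, fitmod.SigaParams(lam=1e-30, max_iters=35))
    rough_before = np.linalg.norm(np.diff(noisy.control, axis=0, n=2))
    rough_after = np.linalg.norm(np.diff(fitted.control, axis=0, n=2))
    assert rough_after < rough_before


def test_fixed_point_near_wall(clean_cylinder):
    """A template already on the phantom wall barely moves in 35 steps."""
    img, _, _ = clean_cylinder
    from siga.image import edge_density
    from siga.skeleton import build_branch_graph, merge_short_branches, skeletonize

    params = fitmod.SigaParams()
    sm = gaussian_smooth(img, params.sigma)
    graph = merge_short_branches(build_branch_graph(skeletonize(img)))
    branch = next(iter(graph))
    init = fitmod.build_templates(branch, image=img, params=params)
    fitted, info = fitmod.evolve(init, image_force(sm), params, density=edge_density(sm))
    disp = np.linalg.norm(fitted.control - init.control, axis=-1)
    assert disp.mean() < 0.5 * min(img.spacing)


def test_interface_columns_stay_shared(jittered_cylinder_fit):
    for surf in jittered_cylinder_fit.surfaces.values():
        p1, p2 = surf.patches()
        np.testing.assert_allclose(p1.control[-1], p2.control[0], atol=0)
        np.testing.assert_allclose(p1.control[0], p2.control[-1], atol=0)


def test_divergence_guard_raises(straight_branch):
    surf = fitmod.build_templates(straight_branch)

    class RunawayField:
        def interp(self, pts):
            return 50.0 * np.asarray(pts)  # outward push growing with position

    params = fitmod.SigaParams(lam=10.0, max_iters=35)
    with pytest.raises(RuntimeError, match="diverged"):
        fitmod.evolve(surf, RunawayField(), params)


# ------------------------------------------------------------- voxelization

def test_voxelize_cylinder_volume(clean_cylinder, cylinder_template):
    img, gt, _ = clean_cylinder
    closed = morphometry.cap_surface(cylinder_template)
    vox = fitmod.voxelize([closed], img)
    expected = gt.volume / img.voxel_volume
    assert vox.data.sum() == pytest.approx(expected, rel=0.05)


def test_voxelize_empty_set(clean_cylinder):
    img, _, _ = clean_cylinder
    out = fitmod.voxelize([], img)
    assert out.data.sum() == 0


def test_voxelize_union_bound(clean_cylinder, cylinder_template):
    img, _, _ = clean_cylinder
    closed = morphometry.cap_surface(cylinder_template)
    shifted = cylinder_template.copy()
    shifted.control += np.array([1.5, 0, 0])
    shifted.centers += np.array([1.5, 0, 0])
    closed2 = morphometry.cap_surface(shifted)
    a = fitmod.voxelize([closed], img).data.sum()
    b = fitmod.voxelize([closed2], img).data.sum()
    u = fitmod.voxelize([closed, closed2], img).data.sum()
    assert max(a, b) <= u <= a + b


def test_voxelize_requires_capped_surfaces(clean_cylinder, cylinder_template):
    img, _, _ = clean_cylinder
    with pytest.raises(TypeError, match="capped"):
        fitmod.voxelize([cylinder_template], img)


# --------------------------------------------------------------------- DICE

def test_dice_identical_masks(clean_cylinder):
    img, _, _ = clean_cylinder
    assert fitmod.dice(img, img) == 1.0


def test_dice_disjoint_masks():
    a = np.zeros((10, 10, 10), dtype=np.uint8)
    b = np.zeros_like(a)
    a[:3], b[6:] = 1, 1
    sp = (1.0, 1.0, 1.0)
    assert fitmod.dice(BinaryImage(a, sp), BinaryImage(b, sp)) == 0.0


def test_dice_partial_overlap_arithmetic():
    a = np.zeros((10, 10, 10), dtype=np.uint8)
    b = np.zeros_like(a)
    a.ravel()[:100] = 1
    b.ravel()[20:120] = 1  # |a|=|b|=100, overlap 80
    assert fitmod.dice(BinaryImage(a, (1, 1, 1)), BinaryImage(b, (1, 1, 1))) == pytest.approx(0.8)


def test_dice_symmetry_and_range():
    rng = np.random.default_rng(9)
    for _ in range(10):
        a = BinaryImage((rng.random((8, 8, 8)) > 0.5).astype(np.uint8), (1, 1, 1))
        b = BinaryImage((rng.random((8, 8, 8)) > 0.5).astype(np.uint8), (1, 1, 1))
        d1, d2 = fitmod.dice(a, b), fitmod.dice(b, a)
        assert d1 == d2 and 0.0 <= d1 <= 1.0


def test_dice_both_empty_undefined():
    e = BinaryImage(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1))
    with pytest.raises(ValueError, match="empty"):
        fitmod.dice(e, e)


def test_dice_shape_mismatch():
    a = BinaryImage(np.ones((4, 4, 4), dtype=np.uint8), (1, 1, 1))
    b = BinaryImage(np.ones((5, 4, 4), dtype=np.uint8), (1, 1, 1))
    with pytest.raises(ValueError, match="shape"):
        fitmod.dice(a, b)


# ------------------------------------------------------------ params / misc

def test_params_validation():
    with pytest.raises(ValueError):
        fitmod.SigaParams(alpha=-1)
    with pytest.raises(ValueError):
        fitmod.SigaParams(max_iters=0)
    p = fitmod.SigaParams.from_dict(
        {"alpha": 1e-2, "beta": 1e-3, "lambda": 0.1, "sigma": 2, "dt": 0.01, "max_iters": 35}
    )
    assert p.lam == 0.1


def test_radial_error_of_fitted_straight_tube(jittered_cylinder_fit):
    """Mean radial error along the mid 80% of the branch below half a voxel."""
    res = jittered_cylinder_fit
    (bid, surf), = res.surfaces.items()
    errs = []
    for v in np.linspace(0.1, 0.9, 9):
        r = sampled_radius(surf, v)
        errs.append(abs(r.mean() - 3.0))
    assert np.mean(errs) < 0.5 * 0.5  # half of the smallest voxel dimension
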