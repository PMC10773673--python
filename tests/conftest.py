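import numpy as np
import pytest

from siga import fit as fitmod
from siga import phantoms
from siga.skeleton import Branch, build_branch_graph


@pytest.fixture(scope="session")
def clean_cylinder():
    """Unjittered straight tube, r=3 mm, L=20 mm, CT-like anisotropic spacing."""
    return phantoms.generate(phantoms.PhantomSpec(kind="cylinder", radius=3.0, length=20.0))


@pytest.fixture(scope="session")
def jittered_cylinder():
    """The benchmark fitting condition: 0.5-voxel boundary jitter, seed 1."""
    return phantoms.generate(
        phantoms.PhantomSpec(kind="cylinder", radius=3.0, length=20.0, noise=0.5, seed=1)
    )


@pytest.fixture(scope="session")
def jittered_cylinder_fit(jittered_cylinder):
    img, _, _ = jittered_cylinder
    return fitmod.fit_mask(img)


@pytest.fixture(scope="session")
def y_phantom():
    return phantoms.generate(phantoms.PhantomSpec(kind="y_bifurcation"))


@pytest.fixture(scope="session")
def elliptic_phantom():
    return phantoms.generate(phantoms.PhantomSpec(kind="elliptic_cylinder", semi_axes=(2.0, 4.0)))


@pytest.fixture(scope="session")
def bent_phantom():
    return phantoms.generate(phantoms.PhantomSpec(kind="bent_tube", radius=3.0, length=20.0))


@pytest.fixture(scope="session")
def straight_branch():
    """Analytic 20 mm branch of radius 3 mm (no image attached)."""
    z = np.linspace(0.0, 20.0, 21)
    nodes = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    return Branch(id=0, nodes=nodes, radii=np.full(len(z), 3.0))


@pytest.fixture(scope="session")
def cylinder_template(straight_branch):
    """Octagonal-template surface on the analytic branch (no image forces)."""
    return fitmod.build_templates(straight_branch)


def graph_from_reference(skel, **kw):
    return build_branch_graph(skel, **kw)
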