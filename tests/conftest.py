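"""Shared phantom fixtures (session-scoped: generation is deterministic)."""

import numpy as np
import pytest

from cardioflow4d.intracardiac import pt_volumes
from cardioflow4d.phantoms import (
    PhantomSpec,
    make_contracting_ellipsoid,
    make_hill_vortex,
    make_plug_tube,
)


@pytest.fixture(scope="session")
def tube():
    """Default plug-tube phantom: (field, ground truth, segmentation)."""
    return make_plug_tube(PhantomSpec(kind="plug_tube"))


@pytest.fixture(scope="session")
def ventricle():
    """Default contracting-ellipsoid phantom, target SV 80 ml, V_ED 140 ml."""
    spec = PhantomSpec(kind="contracting_ellipsoid")
    return make_contracting_ellipsoid(spec)


@pytest.fixture(scope="session")
def ventricle_pt(ventricle):
    """Particle-trace result on the default ventricle phantom."""
    field, gt, seg, planes = ventricle
    return pt_volumes(field, seg, planes["mitral"], planes["aortic"])


@pytest.fixture(scope="session")
def hill():
    """Spherical vortex phantom, radius 20 mm, on a 2 mm grid."""
    spec = PhantomSpec(
        kind="hill_vortex", spacing=(2.0, 2.0, 2.0), shape=(33, 33, 33),
        nt=4, peak_velocity=50.0,
    )
    return make_hill_vortex(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
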