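import numpy as np
import pytest

from mfhplan.bioheat import BioheatParams, PerfusionModel
from mfhplan.mnp import REFERENCE_SUITE, FieldExposure
from mfhplan.phantom import (
    Label,
    PhantomConfig,
    TissueProperties,
    VoxelPhantom,
    builtin_tissue_table,
    generate_phantom,
)


@pytest.fixture(scope="session")
def suite():
    """Characterised magnetite suite (anisotropy field 92 kA/m, water carrier)."""
    return REFERENCE_SUITE


@pytest.fixture(scope="session")
def exposure():
    """Calorimetric exposure: 10.3 kA/m at 171 kHz."""
    return FieldExposure(Hmax=10.3e3, f=171.0e3)


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse 48^3 synthetic breast phantom shared by slower tests."""
    return generate_phantom(PhantomConfig(grid=48, spacing=3.0e-3), seed=1)


def uniform_block(n=12, h=2.0e-3, label=Label.MUSCLE, props=None):
    """All-tissue rectangular block (no exterior), for closed-form thermal checks."""
    labels = np.full((n, n, n), label, dtype=np.uint8)
    table = builtin_tissue_table() if props is None else {label: props}
    return VoxelPhantom(labels, h, table)


@pytest.fixture
def muscle_block():
    return uniform_block()


@pytest.fixture
def insulated_params():
    """No surface convection, no chest-wall clamping, constant perfusion."""
    return BioheatParams(h_conv=0.0, chest_wall="insulated",
                        perfusion=PerfusionModel(kind="constant"))


def conducting_sphere(n, h, radius, sigma):
    """Homogeneous conducting sphere phantom plus centred coordinates."""
    labels = np.zeros((n, n, n), dtype=np.uint8)
    c = n * h / 2.0
    x = (np.arange(n) + 0.5) * h
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    labels[(X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= radius**2] = Label.MUSCLE
    props = {Label.MUSCLE: TissueProperties(1000.0, sigma, 3500.0, 0.5, 0.0, 0.0)}
    return VoxelPhantom(labels, h, props), X - c, Y - c, Z - c


def uniform_axial_A(X, Y, B0):
    """Vector potential of a uniform axial field B0*z_hat: A = B0*rho/2 in phi."""
    A = np.zeros(X.shape + (3,))
    A[..., 0] = -B0 * Y / 2.0
    A[..., 1] = B0 * X / 2.0
    return A
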