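import numpy as np
import pytest

from qrai.grid import Grid, PressureVolume
from qrai.acoustics import AcousticMedium, WaveSolver
from qrai.beams import make_pulse
from qrai.twin import TransducerArray, ImpulseResponse, TwinConfig, TwinOperator


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid2d():
    return Grid((32, 32), (1e-3, 1e-3))


@pytest.fixture
def water2d(grid2d):
    return AcousticMedium(grid2d, c=1500.0, rho=1000.0, grueneisen=0.11)


@pytest.fixture
def hetero2d(grid2d, rng):
    c = 1500.0 + 100.0 * rng.random(grid2d.shape)
    rho = 1000.0 + 80.0 * rng.random(grid2d.shape)
    return AcousticMedium(grid2d, c=c, rho=rho)


@pytest.fixture
def small_twin(water2d):
    """A tiny 2D twin: 4-element line array, short Gaussian pulse, ring-down IR."""
    array = TransducerArray.matrix(
        rows=4,
        cols=1,
        pitch=4e-3,
        center=(0.026, 0.0155),
        normal=(-1.0, 0.0),
        element_size=(3e-3, 3e-3),
        sub_pitch=1e-3,
    )
    return TwinConfig(
        pulse=make_pulse("gaussian", 1e-6, 1e-7),
        array=array,
        ir=ImpulseResponse(kind="damped-sinusoid", f0=1e6, q=2.0),
        medium=water2d,
        duration=2.5e-5,
        pml_width=6,
    )


@pytest.fixture
def small_twin_op(small_twin):
    return TwinOperator(small_twin)


def gaussian_blob(grid: Grid, center_vox, sigma_vox=2.0, amplitude=1.0) -> PressureVolume:
    coords = [np.arange(n) for n in grid.shape]
    mesh = np.meshgrid(*coords, indexing="ij")
    r2 = sum((m - c) ** 2 for m, c in zip(mesh, center_vox))
    return PressureVolume(grid, amplitude * np.exp(-r2 / (2 * sigma_vox**2)), role="p0")
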