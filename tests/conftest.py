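import numpy as np
import pytest

from bindspec.binding import TwoClassModel
from bindspec.simulate import (
    MeltModel,
    NoiseSpec,
    gen_decay,
    gen_melt,
    gen_piecewise_linear,
    gen_scatchard,
    gen_titration,
)

# the single-class parameter set the generators default to
SINGLE = dict(n=2.7, k_d=0.3, eps_bound=0.20)
TWO_CLASS = TwoClassModel(n1=0.79, kd1=0.15, n2=2.2, kd2=1.8)
EPS_412 = 0.257558


@pytest.fixture
def clean_titration():
    return gen_titration(noise=NoiseSpec(sigma=0.0, seed=0))


@pytest.fixture
def noisy_titration():
    return gen_titration(noise=NoiseSpec(sigma=0.005, seed=0))


@pytest.fixture
def clean_scatchard_pair():
    return gen_scatchard(noise=NoiseSpec(sigma=0.0, seed=0))


@pytest.fixture
def clean_mono_decay():
    return gen_decay(baseline=0.05, amplitudes=[1.0], lifetimes=[400.0],
                     t_grid=np.linspace(0.0, 2000.0, 201),
                     noise=NoiseSpec(sigma=0.0, seed=0))


@pytest.fixture
def clean_biexp_decay():
    return gen_decay(baseline=0.0, amplitudes=[1.0, 1.0],
                     lifetimes=[400.0, 2000.0],
                     t_grid=np.linspace(0.0, 8000.0, 401),
                     noise=NoiseSpec(sigma=0.0, seed=0))


@pytest.fixture
def clean_melt():
    return gen_melt(noise=NoiseSpec(sigma=0.0, seed=0))


@pytest.fixture
def clean_three_piece():
    return gen_piecewise_linear([1.5, 6.0], [2.0, 0.5, 0.1],
                                start=(0.0, -12.0),
                                x_grid=np.linspace(0.0, 10.0, 25),
                                noise=NoiseSpec(sigma=0.0, seed=0))
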