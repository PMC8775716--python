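import numpy as np
import pytest

from fibrilmorph.synthetic import (
    AfmBackground,
    AfmSimSpec,
    KineticSimSpec,
    ThermogramSimSpec,
    gen_afm_image,
    gen_kinetic_trace,
    gen_thermogram,
)


@pytest.fixture
def t_grid():
    return np.arange(0.0, 200.5, 1.0)


@pytest.fixture
def clean_trace(t_grid):
    """Noiseless Boltzmann trace with the fast-aggregation parameters."""
    return gen_kinetic_trace(
        KineticSimSpec(y1=0.0, y2=100.0, t_lag=64.8, t_half=80.3, t_grid=t_grid)
    )


@pytest.fixture
def noisy_trace(t_grid):
    return gen_kinetic_trace(
        KineticSimSpec(y1=0.0, y2=100.0, t_lag=64.8, t_half=80.3,
                       t_grid=t_grid, noise_sd=2.0, seed=42)
    )


@pytest.fixture
def T_grid():
    return np.arange(25.0, 110.0 + 0.025, 0.05)


@pytest.fixture
def clean_thermogram(T_grid):
    """Noiseless zero-baseline two-state thermogram."""
    return gen_thermogram(
        ThermogramSimSpec(T_d=66.57, dH_cal=432.2, dH_vH=448.5, T_grid=T_grid)
    )


def small_afm_spec(seed=0, **overrides):
    """Modest 256x256 topography used by most AFM tests (fast)."""
    kwargs = dict(
        image_shape=(256, 256),
        pixel_size=4.0,
        populations=((3.7, 0.0, 6),),
        fibril_width=(10.0, 0.0),
        background=AfmBackground(),
        min_separation=30.0,
        length_range=(150.0, 300.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return AfmSimSpec(**kwargs)


@pytest.fixture
def clean_afm():
    """Six identical noiseless fibrils on a zero background."""
    return gen_afm_image(small_afm_spec())


@pytest.fixture
def rough_afm():
    """Three-population image with tilt, bow and roughness."""
    spec = small_afm_spec(
        seed=7,
        populations=((2.6, 0.4, 5), (3.7, 0.8, 5), (6.1, 1.1, 5)),
        background=AfmBackground(tilt=(0.004, -0.003), bow_amplitude=0.4,
                                 roughness_sd=0.15),
    )
    return gen_afm_image(spec)
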