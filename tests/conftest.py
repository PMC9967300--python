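import numpy as np
import pytest

from sqdimer import DyeParameters, ExtendedDipole
from sqdimer.synthetic import GeneratorConfig, build_template_dye, generate_dimer_trajectory


def make_dipole(center, axis, length=1.4, mu_mag=12.99):
    """ExtendedDipole with bridge termini symmetric about the centre."""
    center = np.asarray(center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return ExtendedDipole(
        center=center,
        mu_hat=axis,
        r=center + 0.5 * length * axis,
        s=center - 0.5 * length * axis,
        length=length,
        mu_mag=mu_mag,
    )


def random_dipole(rng, length=1.4, mu_mag=12.99, box=3.0):
    center = rng.uniform(-box, box, size=3)
    axis = rng.normal(size=3)
    return make_dipole(center, axis, length=length, mu_mag=mu_mag)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng)


@pytest.fixture(scope="session")
def template():
    return build_template_dye()


@pytest.fixture(scope="session")
def dye_params():
    return DyeParameters({"dye_m": 12.99, "dye_n": 12.99})


@pytest.fixture(scope="session")
def noiseless_aa():
    """10-frame jitter-free AA H-aggregate at fixed 0.6 nm separation."""
    cfg = GeneratorConfig(n_frames=10, seed=1, sd_R=0.0, orientation_jitter=0.0,
                          packing="AA")
    return generate_dimer_trajectory(cfg)


@pytest.fixture(scope="session")
def noiseless_ab():
    cfg = GeneratorConfig(n_frames=10, seed=1, sd_R=0.0, orientation_jitter=0.0,
                          packing="AB")
    return generate_dimer_trajectory(cfg)


@pytest.fixture(scope="session")
def small_jittered():
    """50-frame mildly fluctuating AA dimer for series-level tests."""
    cfg = GeneratorConfig(n_frames=50, seed=5, sd_R=0.05, orientation_jitter=8.0)
    return generate_dimer_trajectory(cfg)
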