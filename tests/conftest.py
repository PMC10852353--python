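import numpy as np
import pytest

import stringfe as sf
from stringfe.sampler import SamplerConfig


def harmonic_potential(k=1.0, dimension=1, v0=0.0, masses=None):
    karr = np.broadcast_to(np.asarray(k, dtype=float), (dimension,))

    def energy(x):
        x = np.asarray(x, dtype=float)
        return 0.5 * (karr * x * x).sum(axis=-1) + v0

    def gradient(x):
        return karr * np.asarray(x, dtype=float)

    return sf.Potential(
        dimension=dimension, energy=energy, gradient=gradient,
        masses=np.ones(dimension) if masses is None else np.asarray(masses, float),
        label=f"harmonic(k={k})",
        sampling_box=np.tile([-8.0, 8.0], (dimension, 1)),
    )


def double_well_potential(a=2.0, barrier=3.0):
    """1-D symmetric double well V = barrier * ((x/a)^2 - 1)^2."""

    def energy(x):
        x = np.asarray(x, dtype=float)
        u = (x[..., 0] / a) ** 2 - 1.0
        return barrier * u * u

    def gradient(x):
        x = np.asarray(x, dtype=float)
        u = (x[..., 0] / a) ** 2 - 1.0
        return (4.0 * barrier * u * x[..., 0] / a**2)[..., None]

    return sf.Potential(
        dimension=1, energy=energy, gradient=gradient, masses=np.ones(1),
        label="double-well", sampling_box=np.array([[-3.0 * a, 3.0 * a]]),
    )


def block_se(x, n_blocks=20):
    """Standard error of the mean of a correlated series via blocking."""
    blocks = np.array_split(np.asarray(x), n_blocks)
    means = np.array([b.mean() for b in blocks])
    return means.std(ddof=1) / np.sqrt(n_blocks)


@pytest.fixture(scope="session")
def mb():
    return sf.muller_brown()


# grid-oracle stationary points of the Muller-Brown surface, frozen from a
# 1000x1000 grid search + local refinement (see test_landscapes for the
# in-test re-derivation at lower resolution)
MB_MINIMA = np.array([
    [-0.55822363, 1.44172584],
    [0.62349939, 0.02803776],
    [-0.05001082, 0.46669411],
])
MB_MIN_ENERGIES = np.array([-146.69951721, -108.16672412, -80.76781813])
MB_SADDLES = np.array([
    [-0.82200156, 0.62431280],
    [0.21248658, 0.29298833],
])
MB_SADDLE_ENERGIES = np.array([-40.66484351, -72.24894011])


@pytest.fixture(scope="session")
def deacylation_landscape():
    return sf.make_reaction_landscape(sf.load_stage_spec("deacylation"))


@pytest.fixture
def fast_config():
    return SamplerConfig(n_steps=20_000, burn_in=2_000, friction=20.0, seed=1)
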