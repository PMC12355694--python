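import numpy as np
import pytest

from halomd import (
    LennardJones,
    ParticleSystem,
    ToyMPGNN,
    build_fcc,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fcc108():
    """108-atom argon-like fcc crystal near the LJ equilibrium spacing."""
    return build_fcc(5.26, 3)


@pytest.fixture
def lj():
    return LennardJones(epsilon=0.0103, sigma=3.4, cutoff=5.0, shift=True)


@pytest.fixture
def gnn2():
    return ToyMPGNN(n_species=1, T=2, cutoff=5.0, seed=7)


def random_cluster(n, extent, rng, min_sep=1.5, periodic=False, box=None):
    """Random positions with a guaranteed minimum separation (jittered
    grid construction, so it is O(n) and deterministic given the rng)."""
    cells = int(np.ceil(n ** (1 / 3)))
    pitch = extent / cells
    assert pitch > min_sep + 0.2, "extent too small for requested separation"
    idx = np.stack(
        np.meshgrid(*[np.arange(cells)] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    take = rng.permutation(len(idx))[:n]
    jitter = rng.uniform(-0.5, 0.5, size=(n, 3)) * (pitch - min_sep - 0.1)
    pos = (idx[take] + 0.5) * pitch + jitter
    if box is None:
        box = np.array([extent + 10.0] * 3) if not periodic else np.array([extent] * 3)
    return ParticleSystem(
        positions=pos,
        species=np.zeros(n, dtype=np.int64),
        box=np.asarray(box, dtype=np.float64),
        periodic=np.array([periodic] * 3),
    )
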