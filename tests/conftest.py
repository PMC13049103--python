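import numpy as np
import pytest

from ctpseg.phantom import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free default phantom configuration (30-frame series)."""
    return PhantomConfig(n_frames=30, noise_sd=0.0)


@pytest.fixture(scope="session")
def quiet_case(quiet_config):
    return make_phantom(quiet_config)


@pytest.fixture(scope="session")
def noisy_case():
    return make_phantom(PhantomConfig(n_frames=30, noise_sd=2.0, seed=11))


def make_worked_example():
    """The 4/8-voxel modified-Dice example on a tiny grid.

    |B_I| = 4, |B_O| = 8, prediction with 3 voxels inside B_I, 2 in the
    uncertainty tube and 1 outside B_O, giving D = 10/12.
    """
    shape = (3, 3, 3)
    b_inner = np.zeros(shape, dtype=bool).ravel()
    b_outer = np.zeros(shape, dtype=bool).ravel()
    a = np.zeros(shape, dtype=bool).ravel()
    b_inner[:4] = True  # |B_I| = 4
    b_outer[:8] = True  # |B_O| = 8 (tube = voxels 4..7)
    a[[0, 1, 2, 4, 5, 20]] = True  # 3 inner, 2 tube, 1 outside
    a = a.reshape(shape)
    b_inner = b_inner.reshape(shape)
    b_outer = b_outer.reshape(shape)
    assert b_inner.sum() == 4 and b_outer.sum() == 8
    assert (a & b_inner).sum() == 3
    assert (a & b_outer & ~b_inner).sum() == 2
    assert (a & ~b_outer).sum() == 1
    return a, b_inner, b_outer


def random_nested_triple(rng, max_side=16):
    """Random (A, B_I, B_O) mask triple with B_I contained in B_O."""
    shape = tuple(int(rng.integers(3, max_side + 1)) for _ in range(3))
    b_outer = rng.random(shape) < rng.uniform(0.05, 0.5)
    b_inner = b_outer & (rng.random(shape) < rng.uniform(0.2, 0.9))
    a = rng.random(shape) < rng.uniform(0.05, 0.5)
    return a, b_inner, b_outer


def brute_force_modified_dice(a, b_inner, b_outer):
    """Voxel-by-voxel enumeration oracle for the modified Dice score."""
    n_a = n_bi = overlap = tube_overlap = 0
    for idx in np.ndindex(a.shape):
        in_a = bool(a[idx])
        in_bi = bool(b_inner[idx])
        in_bo = bool(b_outer[idx])
        n_a += in_a
        n_bi += in_bi
        overlap += in_a and in_bo
        tube_overlap += in_a and in_bo and not in_bi
    denom = n_a + n_bi + tube_overlap
    if denom == 0:
        return 1.0 if not b_outer.any() else 0.0
    return 2.0 * overlap / denom


def brute_force_volumes(a, b_inner, b_outer, spacing):
    v = float(np.prod(spacing)) / 1000.0
    correct = missing = excess = 0
    for idx in np.ndindex(a.shape):
        if a[idx] and b_outer[idx]:
            correct += 1
        if b_inner[idx] and not a[idx]:
            missing += 1
        if a[idx] and not b_outer[idx]:
            excess += 1
    return correct * v, missing * v, excess * v
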