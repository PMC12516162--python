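import numpy as np
import pytest

import rimvein as rv


@pytest.fixture(scope="session")
def small_spec() -> rv.PhantomSpec:
    """Desk-scale phantom used across unit tests."""
    return rv.PhantomSpec(volume_shape=(40, 40, 40), n_lesions=4, n_prl=1,
                          n_cvs=1, n_confluent_pairs=1, seed=5)


@pytest.fixture(scope="session")
def phantom_pair(small_spec):
    return rv.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def norm_volume(phantom_pair):
    volume, _ = phantom_pair
    return rv.z_normalize(volume)


@pytest.fixture(scope="session")
def tiny_net() -> rv.NetworkConfig:
    """Very narrow network for fast structural/gradient tests."""
    return rv.NetworkConfig(width_scale=1 / 64, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def ellipsoid_volume(shape=(24, 24, 24), fill=0.0, seed=None):
    """A MultiContrastVolume with an ellipsoidal brain mask and constant (or
    seeded-noise) contrasts, for tests that need full control of intensities."""
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    center = (np.asarray(shape) - 1) / 2
    semi = np.asarray(shape) * 0.45
    mask = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi)) <= 1
    if seed is None:
        data = {n: np.full(shape, fill, np.float32) for n in
                ("t1w", "flair", "epim", "epip")}
    else:
        r = np.random.default_rng(seed)
        data = {n: r.standard_normal(shape).astype(np.float32) for n in
                ("t1w", "flair", "epim", "epip")}
    return rv.MultiContrastVolume(brain_mask=mask, **data)
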