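"""Shared fixtures: small synthetic cubes and independent moment oracles."""

import numpy as np
import pytest

from mnfstream.synthetic import SyntheticSpec, add_noise, make_block_image


def two_pass_moments(pixels: np.ndarray):
    """Independent oracle: corrected two-pass mean/co-moment over bands x N
    pixels (the mean is refined once on centered residuals so the oracle
    itself is accurate for data riding on a large offset)."""
    mu = pixels.mean(axis=1)
    mu = mu + (pixels - mu[:, None]).mean(axis=1)
    centered = pixels - mu[:, None]
    return pixels.shape[1], mu, centered @ centered.T


def naive_moments(pixels: np.ndarray):
    """The cancellation-prone accumulation: co-moment from raw sums of products."""
    n = pixels.shape[1]
    s = pixels.sum(axis=1)
    sp = pixels @ pixels.T
    return n, s / n, sp - np.outer(s, s) / n


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_spec():
    """A 60 x 48 x 24 cube in the standard 4 x 3 block grid."""
    return SyntheticSpec(lines=60, samples=48, bands=24, noise_variance=1e-4, seed=11)


@pytest.fixture(scope="session")
def small_clean(small_spec):
    return make_block_image(small_spec)


@pytest.fixture(scope="session")
def small_noisy(small_spec, small_clean):
    return add_noise(small_clean, small_spec.noise_variance, seed=small_spec.seed + 1)
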