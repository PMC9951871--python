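"""Shared fixtures: small phantoms and prepared training arrays.

Everything is generated programmatically at session start; nothing is read
from disk.  Sizes are deliberately small (64x64, handfuls of images) so the
suite stays desk-fast; corruption-geometry tests build their own 512x512
masks because the quarter-area arithmetic is defined at that size.
"""

import numpy as np
import pytest

from inpaintseg import PhantomSpec, generate_sample, normalize
from inpaintseg.nn import ModelConfig


@pytest.fixture(scope="session")
def mri_spec():
    return PhantomSpec(height=64, width=64, modality="mri", noise_sigma=5.0, seed=7)


@pytest.fixture(scope="session")
def ct_spec():
    return PhantomSpec(height=64, width=64, modality="ct", noise_sigma=10.0, seed=7)


@pytest.fixture(scope="session")
def mri_samples(mri_spec):
    return [generate_sample(mri_spec, i) for i in range(14)]


@pytest.fixture(scope="session")
def mri_arrays(mri_samples):
    """Normalized (N, 1, H, W) images plus (N, H, W) label maps."""
    images = np.stack([normalize(s.image)[0][None] for s in mri_samples])
    labels = np.stack([s.label_map for s in mri_samples])
    return images, labels


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(in_channels=1, depth=3, base_filters=8, groupnorm_groups=4, seed=0)
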