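import numpy as np
import pytest

from wmhseg.io import Volume
from wmhseg.lots_iam import IAMConfig, compute_iam
from wmhseg.phantom import PhantomSpec, generate_phantom
from wmhseg.preprocess import brain_tissue_mask, normalize_volume


@pytest.fixture(scope="session")
def phantom_bundle():
    """One moderately sized lesioned phantom shared across the suite."""
    return generate_phantom(PhantomSpec(shape=(128, 128, 9), lesion_count=6, seed=42))


@pytest.fixture(scope="session")
def phantom_iam(phantom_bundle):
    """Irregularity map of the shared phantom (512 targets per slice/size)."""
    b = phantom_bundle
    return compute_iam(b.flair, b.icv, b.csf, IAMConfig(n_targets=512, seed=7))


@pytest.fixture(scope="session")
def phantom_channels(phantom_bundle, phantom_iam):
    """Normalised FLAIR + IAM channel volumes for network input."""
    b = phantom_bundle
    brain = brain_tissue_mask(b.icv, b.csf)
    return [
        normalize_volume(b.flair, brain),
        Volume(phantom_iam.final_map, b.flair.affine.copy()),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
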