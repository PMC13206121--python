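import numpy as np
import pytest
from hypothesis import settings

from slidemil.synthetic import CohortConfig, generate_cohort

# reproducible hypothesis runs in any environment
settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """60 slides, strong separation, small bags: quick and learnable."""
    cfg = CohortConfig(
        n_slides=60, seed=11, separation=4.0,
        patch_count_range=(8, 40), patch_count_median=20,
    )
    bags, manifest = generate_cohort(cfg)
    return bags, manifest, cfg


@pytest.fixture(scope="session")
def small_features(small_cohort):
    bags, _, _ = small_cohort
    feats = [b.features.astype(np.float64) for b in bags]
    labels = np.array([b.label for b in bags])
    return feats, labels
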