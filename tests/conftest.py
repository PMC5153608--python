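import numpy as np
import pytest

from hogpet import LabeledFeatureSet, extract_descriptor, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """The reference phantom cohort: 30 positive / 30 negative, seed 0.

    Session-scoped because generation at full 80x96x80 resolution is the
    most expensive fixture in the suite and several tests share it.
    """
    bundles, labels = generate_cohort(30, 30, seed=0)
    return bundles, np.array(labels)


@pytest.fixture(scope="session")
def default_cohort_features(default_cohort):
    """3D HOG descriptors (default optimum parameters) of the cohort."""
    bundles, labels = default_cohort
    feats = np.vstack([extract_descriptor(b.volume).values for b in bundles])
    return LabeledFeatureSet(features=feats, labels=labels)
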