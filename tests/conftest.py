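import numpy as np
import pytest

from ppisparse import build_pair_samples, get_profile
from ppisparse.io_formats import sequences_by_id
from ppisparse.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def cp5():
    return get_profile("CP(5)")


@pytest.fixture(scope="session")
def cp8():
    return get_profile("CP(8)")


@pytest.fixture(scope="session")
def cp13():
    return get_profile("CP(13)")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Well-separated synthetic dataset: 30 pairs/class, CP(5), n=1 features."""
    spec = SyntheticSpec(n_pairs=30, separation=0.9, seed=11, length_range=(50, 120))
    records, pairs = generate(spec)
    samples = build_pair_samples(
        sequences_by_id(records), pairs, get_profile("CP(5)"), 1
    )
    return records, pairs, samples
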