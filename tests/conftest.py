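import numpy as np
import pytest

from msipeaks import LengthHistogram, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def bat25(panel):
    return next(m for m in panel if m.name == "Bat25")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_histogram(counts, sample_id="s", tissue="tumor", marker="Bat25"):
    return LengthHistogram(sample_id, tissue, marker, counts)


@pytest.fixture()
def make_hist():
    return make_histogram


def random_histogram(rng, max_bins=12, max_count=500):
    """A random sparse histogram over lengths 5..45."""
    n_bins = int(rng.integers(1, max_bins + 1))
    lengths = rng.choice(np.arange(5, 46), size=n_bins, replace=False)
    return make_histogram(
        {int(k): int(rng.integers(1, max_count)) for k in lengths}
    )
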