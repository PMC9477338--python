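import numpy as np
import pytest

from cisbrs.sequence_model import ImageSequence, ImageSlice, SimilarityParams


def make_slice(slice_id: int, feature, shape=(8, 8)) -> ImageSlice:
    return ImageSlice(slice_id, np.zeros(shape), np.atleast_1d(feature))


def make_sequence(seq_id: int, features) -> ImageSequence:
    return ImageSequence(
        seq_id, [make_slice(i + 1, f) for i, f in enumerate(features)]
    )


def random_sequence(seq_id: int, rng, n_slices=None, dim=3) -> ImageSequence:
    n = n_slices or int(rng.integers(2, 8))
    feats = rng.normal(size=(n, dim))
    return make_sequence(seq_id, feats)


@pytest.fixture
def params():
    return SimilarityParams(0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
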