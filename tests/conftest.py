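import numpy as np
import pytest

from pulseaf.dataset import build_feature_dataset
from pulseaf.preprocess import bandpass_filter
from pulseaf.synthetic import gen_corpus


def corpus_features(n_per_class, seed, modality="ecg", nsr_model=None, af_model=None):
    """Generate a corpus, bandpass each segment, and extract HRV features."""
    kwargs = {}
    if nsr_model is not None:
        kwargs["nsr_model"] = nsr_model
    if af_model is not None:
        kwargs["af_model"] = af_model
    segments, manifest = gen_corpus(
        n_per_class, n_per_class, fs=50.0, modality=modality, seed=seed, **kwargs
    )
    for seg in segments:
        seg.signal = bandpass_filter(seg.signal)
    X, y, kept, dropped = build_feature_dataset(segments)
    return X, y, kept, dropped, manifest


@pytest.fixture(scope="session")
def small_corpus_features():
    """40 NSR + 40 AF clean ECG segments -> features (shared across tests)."""
    X, y, kept, dropped, manifest = corpus_features(40, seed=3)
    return X, y, kept, dropped, manifest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
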