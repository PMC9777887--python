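import numpy as np
import pytest

from specfuse import ClassAlphabet, SpectraMatrix, SyntheticConfig
from specfuse.plsda import encode_labels


@pytest.fixture
def alphabet8():
    return ClassAlphabet()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spectra(rng):
    """3 samples x 4 wavenumbers with codfish-style labels."""
    return SpectraMatrix(
        wavenumbers=np.array([4000.0, 4500.5, 5000.25, 9000.0]),
        intensities=rng.normal(0.5, 0.1, (3, 4)),
        sample_ids=["s1", "s2", "s3"],
        labels=np.array(["ACD", "ACI", "ACD"], dtype=object),
    )


@pytest.fixture
def fast_config():
    """Small-grid synthetic config for quick end-to-end tests."""
    return SyntheticConfig(
        n_classes=8,
        samples_per_class=12,
        nir_grid=(4000.0, 9000.0, 300),
        raman_grid=(1000.0, 2000.0, 150),
        seed=7,
    )


def planted_signal(n_informative=5, n_noise=95, n_per_class=15, n_classes=8,
                   signal_noise=0.3, seed=0):
    """Regression design where only the first ``n_informative`` columns
    carry class information; returns (X, coding, labels, alphabet)."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([f"C{i + 1}" for i in range(n_classes)], n_per_class)
    alphabet = ClassAlphabet(tuple(f"C{i + 1}" for i in range(n_classes)))
    coding = encode_labels(labels, alphabet)
    n = labels.size
    B = rng.normal(0.0, 2.0, (n_informative, n_classes))
    informative = coding.matrix @ B.T + signal_noise * rng.standard_normal(
        (n, n_informative))
    noise = rng.standard_normal((n, n_noise))
    return np.hstack([informative, noise]), coding, labels, alphabet
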