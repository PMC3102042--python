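import numpy as np
import pytest

from gcmsannot import simca, synth
from gcmsannot.spectra import MassSpectrum, normalize_spectrum


@pytest.fixture(scope="session")
def templates():
    return synth.make_default_templates(seed=7)


@pytest.fixture(scope="session")
def training_sets():
    """Five-class training sets at the default sizes (12/10/12/9/13)."""
    return synth.make_default_training_sets(seed=7)


@pytest.fixture(scope="session")
def class_models(training_sets):
    return [simca.fit_class_model(t, r="auto") for t in training_sets]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def spectrum_from_peaks(peaks: dict[int, float]) -> MassSpectrum:
    """Build a spectrum from an {m/z: intensity} dict (zeros elsewhere)."""
    vec = np.zeros(416)
    for mz, inten in peaks.items():
        vec[mz - 85] = inten
    return MassSpectrum(vec)
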