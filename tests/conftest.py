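import logging

import pytest
from hypothesis import settings

from avsync.events import DetectionThresholds, label_corpus
from avsync.synth import NoiseSpec, generate_corpus, make_default_calibration

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

logging.getLogger("avsync").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def calib():
    return make_default_calibration()


@pytest.fixture(scope="session")
def calib_nojitter():
    return make_default_calibration(offset_jitter_sd_ms=0.0)


@pytest.fixture(scope="session")
def thresholds():
    return DetectionThresholds()


@pytest.fixture(scope="session")
def chained_corpus_50(calib):
    """50 noisy repetitions of the 8 chained /aCa/ syllables."""
    return generate_corpus(calib, NoiseSpec(), 50, modes=("chained",), seed=3)


@pytest.fixture(scope="session")
def chained_labels_50(chained_corpus_50, thresholds):
    return label_corpus(chained_corpus_50, thresholds)


@pytest.fixture(scope="session")
def isolated_corpus_50(calib):
    return generate_corpus(calib, NoiseSpec(), 50, modes=("isolated",), seed=4)


@pytest.fixture(scope="session")
def isolated_labels_50(isolated_corpus_50, thresholds):
    return label_corpus(isolated_corpus_50, thresholds)
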