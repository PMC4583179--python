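import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def detector_config():
    from fuzzedge.detector import DetectorConfig

    return DetectorConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240925)


def dense_centroid(aggregates, output_sets, lo=0.0, hi=255.0, n=2560):
    """Independent brute-force centroid: clip, merge by max, integrate on a
    dense grid.  Deliberately written without the package's defuzzify code."""
    z = np.linspace(lo, hi, n)
    q = np.zeros_like(z)
    for label, strength in aggregates.items():
        mu = output_sets[label](z)
        q = np.maximum(q, np.minimum(mu, strength))
    total = q.sum()
    if total == 0:
        raise ValueError("empty aggregate")
    return float((q * z).sum() / total)
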