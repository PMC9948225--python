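import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def random_spectrum(rng, n_peaks=None, mz_range=(41, 220)):
    """Plain random unit-mass spectrum, independent of the synth generators."""
    from terpscreen.spectra import MassSpectrum

    n = int(n_peaks or rng.integers(3, 30))
    lo, hi = mz_range
    mz = np.sort(rng.choice(np.arange(lo, hi + 1), size=n, replace=False))
    inten = rng.uniform(0.5, 100.0, size=n)
    return MassSpectrum(mz, inten)
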