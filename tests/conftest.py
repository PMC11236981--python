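import numpy as np
import pytest

from oftphase.io import Epoch

FS = 5000.0


def make_epoch(samples, fs=FS, **kw) -> Epoch:
    kw.setdefault("parent_id", "test")
    return Epoch(samples=np.asarray(samples, dtype=float), fs=fs, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240710)


@pytest.fixture
def tone_epoch():
    """2-s unit cosine at 1 kHz, fs 5 kHz (carrier frequency of the setup)."""
    n = 10_000
    t = np.arange(n) / FS
    return make_epoch(np.cos(2 * np.pi * 1000.0 * t))


@pytest.fixture
def noise_epoch(rng):
    return make_epoch(rng.standard_normal(10_000))
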