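import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hesimd import HEParams, decrypt_decode, encode_encrypt, keygen

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_env():
    """Default exact-simulator environment: params, keys at N=256."""
    params = HEParams(N=256, backend="sim")
    return params, keygen(params, seed=1)


@pytest.fixture(scope="session")
def fixed_env():
    """Fixed-point backend environment at N=256, default scale."""
    params = HEParams(N=256, backend="fixed")
    return params, keygen(params, seed=1)


@pytest.fixture
def roundtrip():
    """Encode -> decode helper usable with any params/keys pair."""

    def _roundtrip(values, params, keys, n=None):
        ct = encode_encrypt(values, params, keys)
        return decrypt_decode(ct, keys, n if n is not None else len(values))

    return _roundtrip


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
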