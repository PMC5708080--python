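import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ndops
from ndops.io.location import clear_bytes_registry

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def ctx(tmp_path):
    """Fresh default context with isolated preferences."""
    return ndops.create_context(prefs_path=str(tmp_path / "prefs.txt"))


@pytest.fixture(autouse=True)
def _fresh_bytes_registry():
    clear_bytes_registry()
    yield
    clear_bytes_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def assert_images_equal(a, b, tol=0.0):
    """Bitwise for integer sample types, within tol per sample for reals."""
    arr_a = np.asarray(a.to_array(), dtype=np.float64) \
        if a.sample_type.kind == "real" else a.to_array()
    arr_b = np.asarray(b.to_array(), dtype=np.float64) \
        if b.sample_type.kind == "real" else b.to_array()
    if a.sample_type.kind == "real":
        assert np.max(np.abs(arr_a - arr_b)) <= tol
    else:
        assert np.array_equal(arr_a, arr_b)
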