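import numpy as np
import pytest

from causalps._kernels import warmup


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    """Compile the numba kernels once, up front, so individual test
    timings reflect the algorithms rather than JIT latency."""
    warmup()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250922)
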