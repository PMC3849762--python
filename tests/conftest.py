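import numpy as np
import pytest

from ptseq.pt_core import PTMeanParams, pt_sample


@pytest.fixture(scope="session", autouse=True)
def _warm_jit():
    """Compile the numba kernels once so per-test timings are meaningful."""
    pt_sample(5, PTMeanParams(5.0, 2.0, 0.5), 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
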