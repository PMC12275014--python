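import numpy as np
import pytest

from extremenorm import MaxLinearSpec, gen_tail_dependent_zscores


@pytest.fixture(scope="session")
def twofactor_spec() -> MaxLinearSpec:
    """Two-variable max-linear spec with oracle TPDM [[1, .8], [.8, 1]]."""
    return MaxLinearSpec(np.array([[1.0, 0.0], [0.8, 0.6]]))


@pytest.fixture(scope="session")
def twofactor_zscores(twofactor_spec):
    """Large tail-dependent z-score matrix shared across estimator tests."""
    return gen_tail_dependent_zscores(20000, twofactor_spec, seed=20)
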