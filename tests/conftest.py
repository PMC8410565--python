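import numpy as np
import pytest

from rarecell.simulate import FieldSpec, render_field


@pytest.fixture(scope="session")
def small_field():
    """A modest rendered field with all three populations and its truth."""
    spec = FieldSpec(width=600, height=600, n_ctc=5, n_wbc=40, n_debris=10,
                     seed=1)
    return render_field(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
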