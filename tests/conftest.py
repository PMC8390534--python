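import numpy as np
import pytest

from gbopt import REFERENCE_FACTORS, build_mixed_oa, load_reference_dataset


@pytest.fixture(scope="session")
def ref_design():
    return build_mixed_oa(REFERENCE_FACTORS)


@pytest.fixture(scope="session")
def ref_data():
    """The packaged 49-run orthogonal experiment and its measured yields."""
    return load_reference_dataset()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
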