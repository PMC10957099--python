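import numpy as np
import pytest

from fearpipe import protocol


@pytest.fixture(scope="session")
def day1_timeline():
    return protocol.build_timeline("fc_day1")


@pytest.fixture(scope="session")
def day2_timeline():
    return protocol.build_timeline("retrieval_day2", protocol.ProtocolParams(rng_seed=1))


@pytest.fixture(scope="session")
def short_day1():
    """Compressed conditioning session for fast simulation-heavy tests."""
    params = protocol.ProtocolParams(baseline_s=20.0, iti_range_s=(8.0, 12.0),
                                     post_last_cs_s=8.0, rng_seed=3)
    return protocol.build_timeline("fc_day1", params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
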