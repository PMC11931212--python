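import pytest

import astramod as am


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic country bundle."""
    return am.make_synthetic_bundle(1)


@pytest.fixture(scope="session")
def schedule(bundle):
    """Behaviour schedule calibrated to the default bundle."""
    return am.calibrate_schedule(bundle)


@pytest.fixture(scope="session")
def null_bundle():
    """Bundle in which tobacco use carries no excess risk anywhere."""
    return am.make_synthetic_bundle(1, {"null_risks": True})


@pytest.fixture(scope="session")
def null_schedule(null_bundle):
    return am.calibrate_schedule(null_bundle)
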