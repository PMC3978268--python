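import pytest

from zigzag import ModelParams, scan_morphospace, simulate_plant


@pytest.fixture(scope="session")
def wt_params() -> ModelParams:
    """Calibrated wild-type parameter set."""
    return ModelParams()


@pytest.fixture(scope="session")
def wt_ontogeny(wt_params):
    return simulate_plant(wt_params)


@pytest.fixture(scope="session")
def default_morphospace(wt_params):
    """The default 40x30 (dV, delta-V) scan, shared across test modules."""
    return scan_morphospace(wt_params)
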