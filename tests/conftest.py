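import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# leave-one-out deliberately skips members whose deconvolution fails; keep
# the expected warnings out of test output
logging.getLogger("cd2struct.refset").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def basis():
    from cd2struct import make_basis_spectra

    return make_basis_spectra()


@pytest.fixture(scope="session")
def refset_noiseless(basis):
    from cd2struct import make_reference_set

    return make_reference_set(n=30, basis=basis, noise_sigma=0.0, seed=11)


@pytest.fixture(scope="session")
def refset_noisy(basis):
    from cd2struct import make_reference_set

    return make_reference_set(n=30, basis=basis, noise_sigma=0.02, seed=11)
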