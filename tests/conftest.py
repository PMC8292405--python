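import pytest

import photocyclekit as pk


@pytest.fixture(scope="session")
def noiseless_surface():
    """Default three-intermediate surface without noise (exact forward model)."""
    return pk.generate_transient_surface(pk.PhotocycleGroundTruth(noise_sigma=0.0))


@pytest.fixture(scope="session")
def noiseless_titration():
    return pk.generate_titration_series(pk.TitrationGroundTruth(noise_sigma=0.0))
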