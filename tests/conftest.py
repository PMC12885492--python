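import dataclasses

import pytest

from hemotrans import ExperimentProtocol, default_profiles, run_study


@pytest.fixture(scope="session")
def default_study():
    """One full seeded study under the default bench protocol."""
    return run_study(seed=1)


@pytest.fixture(scope="session")
def noiseless_study():
    """Same protocol with every noise source switched off."""
    protocol = ExperimentProtocol(bga_hgb_sigma=0.0, bga_so2_sigma=0.0)
    profiles = [dataclasses.replace(p, noise_sigma=0.0) for p in default_profiles()]
    return run_study(protocol=protocol, profiles=profiles, seed=1)
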