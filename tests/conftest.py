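from __future__ import annotations

import pytest

from psostaff import compute_capacity, default_profile


@pytest.fixture(scope="session")
def profile_75():
    """Packaged default: 75% DPC, three therapeutic groups, tertiary center."""
    return default_profile("capo2022_sw_tertiary_75_25")


@pytest.fixture(scope="session")
def profile_70():
    """Packaged default: 70% DPC variant of the same position."""
    return default_profile("capo2022_sw_tertiary_70_30")


@pytest.fixture(scope="session")
def capacity_75(profile_75):
    return compute_capacity(profile_75)


@pytest.fixture(scope="session")
def capacity_70(profile_70):
    return compute_capacity(profile_70)
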