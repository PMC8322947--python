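import pytest

from baroloop import CohortConfig, MNArcParams, NMArcParams


@pytest.fixture
def mn_mean() -> MNArcParams:
    """Group-mean controller arc of the emulated study."""
    return MNArcParams(g_mn=8.92, ap_mn0=103.0)


@pytest.fixture
def nm_supine() -> NMArcParams:
    """Group-mean plant arc, supine."""
    return NMArcParams(g_nm=0.61, ap_nm0=34.1, angle_deg=0.0)


@pytest.fixture
def nm_hut15() -> NMArcParams:
    """Group-mean plant arc at 15 degrees head-up tilt."""
    return NMArcParams(g_nm=0.36, ap_nm0=33.4, angle_deg=15.0)


@pytest.fixture
def exact_cohort_config() -> CohortConfig:
    """Deterministic cohort: population SDs and measurement noise all zero."""
    return CohortConfig(seed=0).zeroed_noise().zeroed_population_sds()
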