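import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from aeroscore.io_formats import AsvTable, SampleMetadata
from aeroscore.synthetic_data import generate_community

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_table() -> AsvTable:
    return AsvTable(pd.DataFrame([[3, 0], [1, 2]], index=["S1", "S2"],
                                 columns=["ASV_1", "ASV_2"]))


@pytest.fixture
def small_metadata() -> SampleMetadata:
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["S1", "S2", "N1"],
        "location": ["parkA", "parkB", "lab"],
        "sample_type": ["sample", "sample", "laboratory_control"],
        "dna_concentration": [0.8, 1.2, np.nan],
    }).set_index("sample_id"))


@pytest.fixture(scope="session")
def community():
    """One default-shaped synthetic study shared across tests."""
    return generate_community(seed=42)
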