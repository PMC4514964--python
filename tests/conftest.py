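import numpy as np
import pytest

from epiderk import CascadeParameters, SynthConfig, synth_roi_table


@pytest.fixture(scope="session")
def default_params() -> CascadeParameters:
    return CascadeParameters()


@pytest.fixture(scope="session")
def small_roi_table():
    """A small deterministic synthetic ROI table shared across tests."""
    return synth_roi_table(SynthConfig(seed=42, samples_per_patient=120))
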