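import numpy as np
import pytest
from hypothesis import settings

from spikebench.case_studies import run_case_study_1

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# ids of the 5,000 LIF neurons in the case-study-1 layout (generators follow)
LIF_IDS = np.arange(5000)


@pytest.fixture(scope="session")
def cs1_results():
    """Full case-study-1 runs (1 s at dt=0.1 ms) at three seeds.

    Session-scoped: the same rasters feed the refractory-floor check and
    the gamma-band spectrum check.
    """
    return {seed: run_case_study_1(seed)[0] for seed in (1, 2, 3)}
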