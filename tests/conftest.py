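import numpy as np
import pytest

from sqvfs.synthetic_data import SyntheticCohortSpec, synth_cohort


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory):
    """A small but complete synthetic cohort shared across pipeline tests:
    two subjects per group, short trials, fixed seed."""
    out = tmp_path_factory.mktemp("cohort")
    spec = SyntheticCohortSpec(
        group_sizes={"EG": 2, "BF": 2, "BNF": 2},
        audio_duration_s=1.5,
        eeg_duration_s=8.0,
        seed=12345,
    )
    manifest = synth_cohort(spec, out)
    return manifest


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
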