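import numpy as np
import pytest

from sscparc.io_nifti import extract_roi_timeseries
from sscparc.synthetic_data import SimParams, generate_subject

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def subject_high_snr():
    """One clean synthetic subject: strong signal, slight prior mismatch."""
    params = SimParams(snr=4.0, boundary_jitter_vox=0, prior_mismatch_vox=1, seed=11)
    return params, generate_subject(params, 11)


@pytest.fixture(scope="session")
def subject_ts(subject_high_snr):
    _, sub = subject_high_snr
    return extract_roi_timeseries(sub.volume, sub.roi)
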