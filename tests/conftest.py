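import warnings

import numpy as np
import pandas as pd
import pytest

from pupilbias import synthetic
from pupilbias.preproc import PupilTrace


@pytest.fixture(scope="session")
def ground_truth():
    return synthetic.GroundTruth(seed=7, n_trials=400)


@pytest.fixture(scope="session")
def trial_table(ground_truth):
    return synthetic.generate_trial_table(ground_truth)


@pytest.fixture(scope="session")
def clean_session(ground_truth, trial_table):
    """Preprocessed session trace + table (shared by TPR/GLM/SDT tests)."""
    from pupilbias.preproc import PupilPreprocessor

    traces = synthetic.generate_pupil_trace(trial_table, ground_truth)
    prep = PupilPreprocessor(remove_artifacts=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean = [prep.transform_one(t) for t in traces]
    return synthetic.session_trace(clean), trial_table


@pytest.fixture
def flat_trace():
    return PupilTrace(samples=np.full(5000, 100.0), sample_rate=50.0)


@pytest.fixture
def simple_table():
    """Five-trial table on a 50 Hz grid for TPR window tests."""
    cue = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
    rt = np.array([1.0, 2.0, 1.5, 2.5, np.nan])
    return pd.DataFrame({
        "trial_id": np.arange(5), "block": 0, "stimulus": [1, 0, 1, 0, 1],
        "cue_time": cue, "rt": rt, "choice_time": cue + rt,
        "choice": [1, 0, 1, 0, -1], "responded": np.isfinite(rt),
        "tpr_condition": ["low", "high", "low", "high", "low"],
        "orientation": ["CW"] * 5,
    })
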