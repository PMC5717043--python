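import numpy as np
import pandas as pd
import pytest

from oculater import (
    apply_latency_window,
    default_study_params,
    get_design,
    label_previous_trial,
    simulate_experiment,
)
from oculater.trials import COLUMNS


def make_row(**overrides):
    """One schema-valid single-trial row as a dict."""
    row = {
        "participant_id": "p01",
        "experiment": 1,
        "block_id": "b1",
        "trial_index": 1,
        "choice_proportion": 0.0,
        "reward_low": 4,
        "reward_high": 6,
        "congruency": "none",
        "difficulty": "none",
        "cued": False,
        "trial_type": "single",
        "target_side": "left",
        "high_reward_side": "right",
        "contrast_left": np.nan,
        "contrast_right": np.nan,
        "response_side": "left",
        "latency_ms": 200.0,
        "outcome": "hit",
    }
    row.update(overrides)
    return row


def make_table(rows):
    return pd.DataFrame(rows, columns=COLUMNS)


@pytest.fixture(scope="session")
def study_params():
    return default_study_params()


@pytest.fixture(scope="session")
def exp6_table(study_params):
    """Two simulated participants of the latency-distribution experiment."""
    return simulate_experiment(get_design(6), study_params,
                               n_participants=2, seed=7)


@pytest.fixture(scope="session")
def exp6_windowed(exp6_table):
    labeled = label_previous_trial(exp6_table)
    kept, _ = apply_latency_window(labeled)
    return kept
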