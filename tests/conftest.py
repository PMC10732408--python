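import numpy as np
import pandas as pd
import pytest

from bimodal_inference import trialdata as td
from bimodal_inference.simulate import (
    POSTERIOR_MEANS_MOUSE,
    SimulationConfig,
    simulate_cohort,
)
from dataclasses import replace


@pytest.fixture(scope="session")
def m1_cohort():
    """Small observer-model cohort at the default (human) parameters."""
    return simulate_cohort(SimulationConfig(n_agents=20, seed=1234))


@pytest.fixture(scope="session")
def mouse_cohort():
    """Signed-contrast cohort at the mouse parameter set, long series."""
    cfg = SimulationConfig(
        n_agents=12, params=replace(POSTERIOR_MEANS_MOUSE), seed=42,
        trials_min=2000, trials_max=2000,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def toy_frame():
    """2 subjects x 3 trials, binary-category dialect."""
    return pd.DataFrame(
        {
            "subject_id": ["s1"] * 3 + ["s2"] * 3,
            "group_id": ["g1"] * 6,
            "stimulus": [0, 1, 1, 0, 0, 1],
            "choice": [0, 1, 0, 1, 0, 1],
            "confidence": [0.5, 0.7, 0.2, 0.9, 0.1, 0.6],
        }
    )


def make_series(stimulus, choice, dialect=td.BINARY_CATEGORY, subject="s", group="g", **kw):
    return td.TrialSeries(
        subject_id=subject, group_id=group,
        stimulus=np.asarray(stimulus, dtype=float),
        choice=np.asarray(choice), dialect=dialect, **kw,
    )
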