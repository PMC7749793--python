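import numpy as np
import pandas as pd
import pytest

from eegcomplexity.cognition import ScorePanel
from eegcomplexity.simulate import (
    SimulationConfig,
    SubjectSpec,
    reduced_config,
    simulate_cohort,
    simulate_eeg,
)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimulationConfig:
    """A small but structurally complete cohort configuration."""
    return reduced_config(
        SimulationConfig(n_pd=6, n_hc=4, seed=1234), n_channels=10
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    return simulate_cohort(tiny_cfg)


@pytest.fixture(scope="session")
def short_recording(tiny_cfg):
    """One 172 s, 10-channel eyes-open recording."""
    spec = SubjectSpec(
        subject_id="FIX01",
        group="PD",
        age=66.0,
        education=14.0,
        sex="f",
        sleepiness=3.0,
        theta_complexity={"EC": 5.0, "EO": 5.0},
    )
    return simulate_eeg(spec, "EO", tiny_cfg)


@pytest.fixture()
def toy_panel() -> ScorePanel:
    """Two subjects x four tests (one per domain), hand-checkable numbers.

    Baselines are 0 and 2 for every test (cohort baseline sd = sqrt(2));
    every reliability is 0.5, so S_diff = sqrt(2 * (sqrt(2)*sqrt(0.5))**2)
    = sqrt(2) for each test.
    """
    tests = pd.DataFrame(
        {
            "test": ["t_att", "t_exe", "t_vis", "t_wm"],
            "domain": [
                "attention",
                "executive",
                "visuoconstructive",
                "working_memory",
            ],
            "higher_is_better": [False, True, True, True],
            "reliability": [0.5, 0.5, 0.5, 0.5],
        }
    )
    s2 = float(np.sqrt(2))
    rows = []
    # subject s1: planted changes; subject s2: no change at all
    deltas_s1 = {"t_att": s2, "t_exe": -s2, "t_vis": 0.0, "t_wm": s2}
    for test in tests["test"]:
        for subject, base in (("s1", 0.0), ("s2", 2.0)):
            delta = deltas_s1[test] if subject == "s1" else 0.0
            rows += [
                {"subject": subject, "test": test, "timepoint": "baseline", "value": base},
                {"subject": subject, "test": test, "timepoint": "m6", "value": base},
                {"subject": subject, "test": test, "timepoint": "y3", "value": base + delta},
            ]
    return ScorePanel(scores=pd.DataFrame(rows), tests=tests)
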