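import numpy as np
import pytest

from lapref import synthetic_cohort as sc
from lapref import task_design as td
from lapref.keypress_analysis import KeypressEvent, KeypressSession, TrialRecord, compute_viewtime


@pytest.fixture(scope="session")
def conditions():
    return td.default_conditions()


@pytest.fixture(scope="session")
def run25(conditions):
    """A counterbalanced 25-block run with its timeline (fixed seed)."""
    seq = td.generate_counterbalanced_sequence(conditions, 25, seed=11)
    return seq, td.build_timeline(seq, seed=11)


def make_session(net_by_picture, subject_id="s1", default=6.0):
    """Session from {category: {picture_id: (n_approach, n_avoid)}}."""
    trials = []
    for cat, pics in net_by_picture.items():
        for pid, (n_app, n_avd) in pics.items():
            trials.append(
                TrialRecord(
                    picture_id=pid,
                    category=cat,
                    n_approach=n_app,
                    n_avoid=n_avd,
                    viewtime=compute_viewtime(n_app, n_avd, default=default),
                )
            )
    return KeypressSession(subject_id=subject_id, trials=trials)


@pytest.fixture
def session_factory():
    return make_session
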