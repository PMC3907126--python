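import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

import raads14 as r14
from raads14.simulate import calibrate_defaults, generate_cohort


@pytest.fixture(scope="session")
def inst():
    return r14.raads14()


def make_record(answers_by_id, subject_id="s", group="ASD"):
    return r14.ResponseRecord(subject_id=subject_id, group=group, answers=dict(answers_by_id))


def record_from_scores(scores_by_id, inst, subject_id="s", group="ASD"):
    """Build a record whose *recovered* item scores equal scores_by_id."""
    answers = {}
    for item in inst.items:
        s = scores_by_id.get(item.item_id)
        if s is None:
            answers[item.item_id] = None
        else:
            fwd = 3 - s if item.reversed else s
            answers[item.item_id] = inst.category_for_score(fwd)
    return make_record(answers, subject_id=subject_id, group=group)


@pytest.fixture(scope="session")
def calibrated_cohort():
    """A clean (uncontaminated) calibrated four-group cohort, 2000/group."""
    cfg = calibrate_defaults(
        seed=123, n_per_group=2000, straight_line_rate=0.0, missing_rate=0.0
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20131209)
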