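import numpy as np
import pytest

import sugarkit as sk


@pytest.fixture(scope="session")
def default_cohort():
    """One large cohort under the default study conditions, shared across
    tests that only read it."""
    return sk.simulate_cohort(sk.SimConfig(n_participants=5000, seed=42))


@pytest.fixture
def make_glip_series():
    """Factory for small glipizide series with explicit glucose (and
    optional insulin/symptom) values on a schedule prefix."""

    def _make(
        glucose,
        times=(0, 30, 60, 90, 120, 180, 240),
        insulin=None,
        hypo=None,
        neuro=None,
        pid="p1",
    ):
        k = len(glucose)
        return sk.ChallengeSeries(
            participant_id=pid,
            challenge="glipizide",
            times=np.asarray(times[:k]),
            glucose=np.asarray(glucose, dtype=float),
            insulin=None if insulin is None else np.asarray(insulin, dtype=float),
            symptom_hypoglycemic=None if hypo is None else np.asarray(hypo, bool),
            symptom_neuroglycopenic=None if neuro is None else np.asarray(neuro, bool),
        )

    return _make


@pytest.fixture
def completer():
    return sk.ParticipantRecord(
        participant_id="p1",
        age=50.0,
        sex="female",
        ethnicity="non_hispanic_white",
        bmi=31.0,
        received_glipizide=True,
        termination_time=240,
        rescued=False,
        metformin_doses=4,
        attended_visit2=True,
    )
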