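from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from innercrowd.pipeline import ParticipantRecord, QuestionSet

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def qs() -> QuestionSet:
    return QuestionSet.default()


@pytest.fixture()
def make_record(qs):
    """Factory for hand-built participant records with sensible defaults."""

    counter = {"i": 0}

    def _make(guess1=None, guess2=None, condition="immediate", **kw) -> ParticipantRecord:
        counter["i"] += 1
        rng = np.random.default_rng(counter["i"])
        if guess1 is None:
            guess1 = rng.uniform(0, 100, len(qs))
        if guess2 is None:
            guess2 = rng.uniform(0, 100, len(qs))
        return ParticipantRecord(
            participant_id=kw.pop("participant_id", f"p{counter['i']:03d}"),
            condition=condition,
            guess1=np.asarray(guess1, float),
            guess2=np.asarray(guess2, float),
            **kw,
        )

    return _make
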