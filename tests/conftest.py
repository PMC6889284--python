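"""Shared fixtures and deterministic hypothesis settings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from agreenet.io import AnswerKey, ResponseMatrix
from agreenet.profiles import ModuleCatalog

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def small_rm() -> ResponseMatrix:
    """Four students, three questions, options A-C; s4 has one missing."""
    choices = pd.DataFrame(
        {
            "q1": ["A", "A", "B", "C"],
            "q2": ["B", "B", "B", "A"],
            "q3": ["C", "A", "C", np.nan],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    choices.index.name = "student_id"
    choices.columns.name = "question_id"
    opts = {q: ("A", "B", "C") for q in choices.columns}
    return ResponseMatrix(choices=choices, options=opts)


@pytest.fixture
def small_key() -> AnswerKey:
    return AnswerKey(correct={"q1": "A", "q2": "B", "q3": "C"})


@pytest.fixture
def small_cat() -> ModuleCatalog:
    return ModuleCatalog(
        modules={
            "m1": frozenset({("q1", "B"), ("q2", "A"), ("q3", "A")}),
            "m2": frozenset({("q1", "C"), ("q2", "C"), ("q3", "B")}),
        },
        display_names={"m1": "conception one", "m2": "conception two"},
    )
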