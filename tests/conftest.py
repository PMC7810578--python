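import numpy as np
import pytest

from tymbal.tymbal_model import (
    ClickEvent,
    IndividualProfile,
    default_mc_template,
    synthesize_click_train,
)


@pytest.fixture(scope="session")
def template():
    return default_mc_template()


@pytest.fixture(scope="session")
def train_45():
    """A synthesized click train targeting a 45% maximum duty cycle."""
    return synthesize_click_train(IndividualProfile("Bertholdia trigona", 45.0, seed=7), 0.4)


def make_uniform_clicks(n, duration=0.0003, spacing=0.000533, start=0.0):
    """n evenly spaced clicks; spacing must exceed duration."""
    return [ClickEvent(start + i * spacing, duration) for i in range(n)]
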