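import numpy as np
import pytest

from varbind.models import (
    BackgroundDistribution,
    FirstOrderTFFM,
    PositionCountMatrix,
    pcm_to_pwm,
)


@pytest.fixture
def uniform_bg():
    return BackgroundDistribution.uniform()


@pytest.fixture
def toy_pcm():
    """A 4-column matrix with an unambiguous consensus ACGT."""
    counts = np.array([
        [80, 5, 5, 10],
        [10, 80, 5, 10],
        [5, 10, 80, 10],
        [5, 5, 10, 70],
    ], dtype=float)
    return PositionCountMatrix(counts, tf_name="TOY", model_id="TOY.1",
                               source="test")


@pytest.fixture
def toy_pwm(toy_pcm, uniform_bg):
    return pcm_to_pwm(toy_pcm, uniform_bg, pseudocount_scale=1.0)


@pytest.fixture
def toy_tffm():
    """Small first-order TFFM with a CA-favouring 2-position motif."""
    mc = np.array([
        [[0.1, 0.7, 0.1, 0.1]] * 4,
        [[0.8, 0.1, 0.05, 0.05],
         [0.7, 0.1, 0.1, 0.1],
         [0.6, 0.2, 0.1, 0.1],
         [0.5, 0.3, 0.1, 0.1]],
    ])
    return FirstOrderTFFM(
        background_emission=np.full(4, 0.25),
        background_conditional=np.full((4, 4), 0.25),
        motif_conditional=mc,
        background_self_transition=0.9,
        motif_entry=0.1,
        tf_name="TOY", model_id="TOY.tffm", source="test")
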