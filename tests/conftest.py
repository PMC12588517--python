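import numpy as np
import pytest

from interceptsim import TaskConfig


@pytest.fixture
def cfg():
    return TaskConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_measures_row(participant, group, trial_index, kind, ordinal,
                      ce, tpv, ncor):
    return {
        "participant": participant, "group": group,
        "trial_index": trial_index, "kind": kind,
        "perturbation_ordinal": ordinal, "ce": ce, "tpv": tpv, "ncor": ncor,
    }
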