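import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from errpkit.io import EpochSet
from errpkit.pipeline import condition_epochs
from errpkit.synth import GeneratorConfig, generate_epochs


def make_epochs(data, labels, fs=1000.0, t0_offset=0.0, channel_names=None, subject_id="t"):
    data = np.asarray(data, dtype=float)
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(
        data=data,
        fs=fs,
        t0_offset=t0_offset,
        labels=np.asarray(labels, dtype=object),
        channel_names=channel_names,
        subject_id=subject_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_subject():
    """One synthetic subject at generator defaults, raw epochs + truth."""
    return generate_epochs(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def conditioned_subject(default_subject):
    """The same subject after the full conditioning chain."""
    return condition_epochs(default_subject[0])


@pytest.fixture(scope="session")
def two_class_epochs():
    """Small separable two-class set: class difference on channels 1 and 3."""
    rng = np.random.default_rng(99)
    n, c, s = 60, 5, 80
    data = rng.standard_normal((n, c, s))
    labels = np.array(["error"] * 20 + ["correct"] * 40, dtype=object)
    bump = np.exp(-0.5 * ((np.arange(s) - 40) / 8.0) ** 2)
    data[:20, 1] += 2.0 * bump
    data[:20, 3] -= 1.5 * bump
    return make_epochs(data, labels)
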