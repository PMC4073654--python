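import numpy as np
import pytest

from longswe.design import LongitudinalDesign
from longswe import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def balanced_small():
    """Balanced two-group design: 12 subjects, 3 visits, polynomial effects."""
    return sim.build_balanced_design(12, 3)


@pytest.fixture
def balanced_mid():
    return sim.build_balanced_design(50, 5)


def make_onesample(m: int) -> LongitudinalDesign:
    """One group, one observation per subject, intercept-only."""
    return LongitudinalDesign(
        X=np.ones((m, 1)),
        subject_id=np.arange(m),
        group_id=np.zeros(m, dtype=int),
        visit_cat=np.zeros(m, dtype=int),
        time=np.zeros(m),
        column_names=("intercept",),
    )


@pytest.fixture
def onesample20():
    return make_onesample(20)
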