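import numpy as np
import pytest

from sdefc import (
    ConditionEffect,
    NetworkScheme,
    StudyDesign,
    simulate_study,
)
from sdefc.design import DEFAULT_NETWORKS


@pytest.fixture(scope="session")
def scheme8() -> NetworkScheme:
    """Default desk-scale scheme: 8 networks of 5 nodes."""
    return NetworkScheme.balanced(5, DEFAULT_NETWORKS)


@pytest.fixture(scope="session")
def scheme2() -> NetworkScheme:
    """Tiny scheme for fast end-to-end runs: 2 networks of 3 nodes."""
    return NetworkScheme.balanced(3, DEFAULT_NETWORKS[:2])


@pytest.fixture(scope="session")
def null_study(scheme2):
    """A small null study (no condition effect): 6 participants, T=100/half."""
    design = StudyDesign(
        participants=tuple(f"s{i:02d}" for i in range(6)),
        timepoints_per_half=100,
        seed=7,
    )
    scans = simulate_study(design, scheme2, ConditionEffect.null(), seed=7)
    return design, scans


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
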