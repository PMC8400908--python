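"""Shared fixtures: the margin-exact demo cohort and cached simulations."""

import pytest

from pgxbleed import published
from pgxbleed.synthetic_cohort import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def demo_cohort():
    """142-subject cohort reconstructed from the published margins."""
    return published.reconstruct_demo_cohort()


@pytest.fixture(scope="session")
def sim_default_10k():
    """Default-condition synthetic cohort, n = 10,000 (haplotype work)."""
    return simulate_cohort(SimConfig(n_subjects=10_000, seed=42))


@pytest.fixture(scope="session")
def sim_default_50k():
    """Default-condition synthetic cohort, n = 50,000 (frequency checks)."""
    return simulate_cohort(SimConfig(n_subjects=50_000, seed=7))


@pytest.fixture(scope="session")
def sim_small():
    """Study-sized synthetic cohort (n = 142)."""
    return simulate_cohort(SimConfig(seed=11))
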