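"""Shared fixtures: simulated cohorts and screen products.

Cohort-level fixtures are session-scoped because simulation is the dominant
cost of the suite; tests must not mutate them.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from hgtscan.pipeline import genotype_cohort, screen_cohort  # noqa: F401 (re-exported)
from hgtscan.simcohort import SimConfig, simulate_cohort

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort under the full default study conditions (47 tumors,
    11-block element)."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_genotypes(default_cohort):
    return genotype_cohort(default_cohort)


@pytest.fixture(scope="session")
def default_screen(default_cohort):
    return screen_cohort(default_cohort)
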