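"""Shared fixtures: built-in layouts, a desk-scale simulated cohort and its
full analysis. The expensive cohort fixtures are session-scoped so the whole
suite pays for simulation and analysis once."""

from __future__ import annotations

import pytest

from capcompare import montage
from capcompare.pipeline import PipelineConfig, run_study
from capcompare.synthdata import CapType, simulate_session

COHORT_SEED = 11
N_SUBJECTS = 10


@pytest.fixture(scope="session")
def ten_twenty():
    return montage.builtin_layout("ten_twenty")


@pytest.fixture(scope="session")
def equidistant():
    return montage.builtin_layout("equidistant")


@pytest.fixture(scope="session")
def combined(ten_twenty, equidistant):
    return montage.combined_layout(ten_twenty, equidistant)


@pytest.fixture(scope="session")
def desk_config():
    """Desk-scale study conditions: 10 subjects, ten-fold shorter segments."""
    return PipelineConfig.desk_scale(n_subjects=N_SUBJECTS, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def study(desk_config):
    """(cohort, analyzed pairs, study report) under the desk-scale conditions."""
    return run_study(desk_config)


@pytest.fixture(scope="session")
def one_session(desk_config, ten_twenty):
    """A single dry-cap session on the ten-twenty layout, with its metadata."""
    return simulate_session(
        desk_config.simulation, "S900", CapType.DRY, ten_twenty, seed=900
    )
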