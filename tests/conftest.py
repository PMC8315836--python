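import numpy as np
import pandas as pd
import pytest

import crowdwise as cw


@pytest.fixture(scope="session")
def questions():
    return cw.generate_questions(42, seed=0)


@pytest.fixture(scope="session")
def design():
    return cw.build_design(seed=0)


@pytest.fixture(scope="session")
def presets():
    return cw.load_presets()


@pytest.fixture(scope="session")
def simulation(design, questions, presets):
    """50 replicate experiments with the calibrated treatment parameters.

    Shared across the recovery and qualitative tests: ~5e4 sensitivity
    draws per (treatment, tau) condition.
    """
    return cw.simulate(design, questions, presets, n_runs=50, seed=0)


@pytest.fixture(scope="session")
def kept_records(simulation):
    kept, _, _ = cw.restrict_sensitivities(simulation.records)
    return kept


@pytest.fixture(scope="session")
def tiny_setup():
    """A miniature but structurally complete experiment for fast tests:
    3 groups/treatment, groups of 4, tau in {1, 2, 3}, 6 questions."""
    questions = cw.generate_questions(6, seed=7)
    design = cw.build_design(
        n_groups_per_treatment=3,
        group_size=4,
        tau_levels=(1, 2, 3),
        n_questions=6,
        seed=7,
    )
    return questions, design
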