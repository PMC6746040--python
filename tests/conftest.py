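"""Shared fixtures: synthetic cohorts and reference templates.

The full-size reference (19 donors x 10,000 events, 10x10 grid) is
expensive enough that it is built once per session and reused; its build
wall-time is kept so the structural test can assert the runtime budget.
"""

import time

import numpy as np
import pytest
from hypothesis import settings

import marrowmap as mm
from marrowmap.annotate import DEFAULT_RULES, label_nodes
from marrowmap.simulate import CohortSpec, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return mm.default_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """5 donors x 3,000 events — fast material for unit tests."""
    return generate_cohort(
        CohortSpec(n_samples=5, events_per_sample=3000, seed=11), panel=panel
    )


@pytest.fixture(scope="session")
def small_template(panel, small_cohort):
    return mm.build_reference(small_cohort, panel, seed=11)


@pytest.fixture(scope="session")
def full_cohort(panel):
    """The default study cohort: 19 donors x 10,000 events."""
    return generate_cohort(CohortSpec(seed=42), panel=panel)


@pytest.fixture(scope="session")
def timed_full_build(panel, full_cohort):
    """(template, build_seconds) for the default full-size reference."""
    t0 = time.perf_counter()
    template = mm.build_reference(full_cohort, panel, seed=42)
    elapsed = time.perf_counter() - t0
    template.node_labels = label_nodes(template, DEFAULT_RULES)
    return template, elapsed


@pytest.fixture(scope="session")
def full_template(timed_full_build):
    return timed_full_build[0]


@pytest.fixture(scope="session")
def full_ranges(full_template):
    return mm.compute_normal_ranges(full_template)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
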