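"""Shared fixtures: synthetic bundles at several scales.

All fixtures are generated programmatically; the heavy paper-scale
bundle and its base-case run are session-scoped so the suite pays for
them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from oamodel import run_base_case
from oamodel.cohort import build_cohort
from oamodel.synthetic import ScenarioConfig, generate_input_bundle


@pytest.fixture(scope="session")
def paper_like():
    """Full eight-stratum bundle at realistic national scale."""
    return generate_input_bundle(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def paper_cohort(paper_like):
    return build_cohort(paper_like)


@pytest.fixture(scope="session")
def base_result(paper_like, paper_cohort):
    return run_base_case(paper_like, paper_cohort)


@pytest.fixture(scope="session")
def null_inputs():
    return generate_input_bundle(ScenarioConfig(seed=2, profile="null_effect"))


@pytest.fixture(scope="session")
def small_inputs():
    """Two strata, short horizon: cheap enough for repeated PSA runs."""
    return generate_input_bundle(
        ScenarioConfig(seed=11, n_strata_override=2, max_age=75)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
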