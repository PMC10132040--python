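"""Shared fixtures: a small synthetic cohort and its feature matrix.

Everything is generated programmatically at session start; no data files.
"""

import pytest

from emastress.app_log import CategoryMap
from emastress.features import build_feature_matrix
from emastress.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def category_map():
    return CategoryMap.from_yaml()


@pytest.fixture(scope="session")
def demo_config():
    return SyntheticConfig(n_persons=10, n_days=14, seed=42)


@pytest.fixture(scope="session")
def demo_cohort(demo_config):
    events, ema, truth = generate_cohort(demo_config)
    return events, ema, truth


@pytest.fixture(scope="session")
def demo_matrix(demo_config, demo_cohort):
    events, ema, _ = demo_cohort
    matrix, _ = build_feature_matrix(
        events, ema, lockdown_date=demo_config.lockdown_date
    )
    return matrix
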