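import dataclasses

import numpy as np
import pytest

from hrsgrowth.config import (default_bivariate_growth, default_design,
                              default_measurement, default_univariate_growth)
from hrsgrowth.simulate import generate_item_panel, generate_score_panel


@pytest.fixture(scope="session")
def growth():
    return default_bivariate_growth()


@pytest.fixture(scope="session")
def measurement():
    return default_measurement()


def make_design(n, seed, **overrides):
    return dataclasses.replace(default_design(n, seed=seed), **overrides)


@pytest.fixture(scope="session")
def score_panel(growth):
    """Mid-sized bivariate factor-score panel without attrition."""
    design = make_design(2000, seed=42, retention=(1.0, 1.0, 1.0))
    return generate_score_panel(growth, design)


@pytest.fixture(scope="session")
def item_panel(growth, measurement):
    """Item-level panel with default (MCAR) attrition."""
    design = make_design(4000, seed=7)
    return generate_item_panel(growth, measurement, design)


@pytest.fixture(scope="session")
def big_item_panel(growth, measurement):
    """Large panel for loading-recovery and Bartlett properties."""
    design = make_design(20000, seed=3)
    return generate_item_panel(growth, measurement, design)
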