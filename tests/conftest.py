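import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import lifecap as lc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cfg():
    return lc.default_config()


@pytest.fixture(scope="session")
def small_cohort(default_cfg):
    """Default-structure cohort at a size cheap enough for unit tests."""
    return lc.generate_cohort(default_cfg.replace(n=3000, seed=42))


@pytest.fixture(scope="session")
def covariate_names(default_cfg):
    return [c.name for c in default_cfg.covariates]


@pytest.fixture(scope="session")
def references(default_cfg):
    return {c.name: c.reference for c in default_cfg.covariates}


@pytest.fixture(scope="session")
def category_map(default_cfg):
    return {c.name: c.category for c in default_cfg.covariates}


@pytest.fixture(scope="session")
def early_life_names(default_cfg):
    return [c.name for c in default_cfg.by_category("early_life")]


@pytest.fixture(scope="session")
def ses_names(default_cfg):
    return [c.name for c in default_cfg.by_category("current_ses")]


def random_design_cohort(rng, n=60, k=3):
    """Small random cohort with categorical determinants, a ranking
    variable and a noisy outcome; used by decomposition property tests."""
    df = pd.DataFrame(
        {
            f"f{j}": pd.Categorical(
                rng.choice(["a", "b", "c"], size=n), categories=["a", "b", "c"]
            )
            for j in range(k)
        }
    )
    df["rankvar"] = rng.standard_normal(n)
    beta = rng.normal(scale=0.5, size=(k, 2))
    y = rng.standard_normal(n) * 0.5 + 1.0
    for j in range(k):
        for l, lvl in enumerate(["b", "c"]):
            y = y + beta[j, l] * (df[f"f{j}"] == lvl).to_numpy()
    df["y"] = y
    return df
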