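"""Shared fixtures: planted-signal synthetic datasets and a compact search space."""

import numpy as np
import pytest

from qcar import synthetic
from qcar.dataset import align
from qcar.search import SearchSpace

#: Indices of the planted drivers in the standard planted-signal dataset.
NEG_DRIVER = 0  # beta < 0: lowers EC50, raises activity (positive contributor)
POS_DRIVER = 1  # beta > 0: raises EC50, lowers activity (negative contributor)


def planted_spec(seed: int = 7, noise_sd: float = 0.05) -> synthetic.GeneratorSpec:
    """Strong two-driver generative setting used across the suite."""
    return synthetic.GeneratorSpec(
        n_oils=61,
        n_components=40,
        dominance=2.5,
        driver_set=[(NEG_DRIVER, -0.04), (POS_DRIVER, 0.04)],
        noise_sd=noise_sd,
        intercept_log10=0.0,
        censor_limit=1.0,
        seed=seed,
    )


def planted_arrays(seed: int = 7, noise_sd: float = 0.05):
    """(comps, values, censored) aligned for direct search-level calls."""
    spec = planted_spec(seed=seed, noise_sd=noise_sd)
    comps, records = synthetic.generate_dataset(spec)
    return align(comps, records, "dpph")


@pytest.fixture(scope="session")
def planted_dataset():
    spec = planted_spec()
    comps, records = synthetic.generate_dataset(spec)
    return spec, comps, records


@pytest.fixture(scope="session")
def planted_xy(planted_dataset):
    _, comps, records = planted_dataset
    return align(comps, records, "dpph")


@pytest.fixture()
def compact_space() -> SearchSpace:
    """Small configurable space; budgets 100/1000 exhaust it quickly."""
    return SearchSpace(
        grids={
            "decision_tree": {
                "max_depth": (None, 3, 5),
                "min_samples_leaf": (1, 3),
            },
            "knn": {"n_neighbors": (3, 5), "weights": ("uniform", "distance")},
            "random_forest": {
                "n_estimators": (50,),
                "max_depth": (None, 3),
                "min_samples_leaf": (1,),
            },
        },
        thresholds=(0.1, 0.25, 0.5, 1.0),
        n_levels=(0, 1),
        scaling_flags=(False, True),
        pca_levels=(None, 0.90),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230929)
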