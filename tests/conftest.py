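import numpy as np
import pandas as pd
import pytest

from reopair import (
    ExpressionMatrix,
    SimulationConfig,
    SurvivalTable,
    find_stable_pairs,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_matrix():
    """4 genes x 3 samples with a fully consistent ordering A > B > C > D."""
    values = np.array(
        [
            [9.0, 9.5, 8.8],
            [7.0, 7.2, 6.9],
            [5.0, 5.5, 4.9],
            [3.0, 3.1, 2.8],
        ]
    )
    return ExpressionMatrix(["A", "B", "C", "D"], ["s1", "s2", "s3"], values)


@pytest.fixture
def toy_surv():
    return SurvivalTable(
        [f"s{i}" for i in range(6)],
        [3.0, 5.0, 7.0, 11.0, 13.0, 17.0],
        [1, 1, 0, 1, 0, 1],
    )


def small_config(seed: int, **overrides) -> SimulationConfig:
    """Scaled-down simulation defaults shared across the suite."""
    kwargs = dict(
        n_genes=120,
        n_normal=100,
        n_tumor=300,
        noise_sd=0.5,
        n_pathways=20,
        pathway_size_min=8,
        pathway_size_max=15,
        n_planted_pairs=3,
        reversal_prob=0.3,
        prognostic_hr=4.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def seeded_cohort():
    """One shared simulated cohort (with stable pairs) for read-only tests."""
    cfg = SimulationConfig(
        n_genes=120,
        n_normal=100,
        n_tumor=300,
        n_pathways=20,
        pathway_size_min=8,
        pathway_size_max=15,
        seed=2024,
        benefit_pair=True,
    )
    cohort = simulate_cohort(cfg)
    cohort["stable"] = find_stable_pairs(cohort["normal"])
    cohort["config"] = cfg
    return cohort
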