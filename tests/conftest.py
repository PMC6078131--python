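import numpy as np
import pandas as pd
import pytest

import seropanel as sp


@pytest.fixture(scope="session")
def small_config() -> sp.SimConfig:
    """Scaled-down cohort used across module tests."""
    return sp.SimConfig.recovery_default(seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sp.generate_cohort(small_config)


@pytest.fixture(scope="session")
def normalized(small_cohort):
    dataset, truth = small_cohort
    matrix, qc = sp.normalize_pipeline(dataset)
    return matrix, qc, truth


@pytest.fixture(scope="session")
def calls_and_scores(normalized):
    matrix, _, truth = normalized
    cutoffs = sp.compute_cutoffs(matrix)
    calls = sp.dichotomize(matrix, cutoffs)
    scores = sp.biomarker_scores(calls, matrix.labels)
    return cutoffs, calls, scores, matrix, truth


def random_matrix(rng: np.random.Generator, n_samples: int, n_antigens: int,
                  n_patients: int | None = None) -> sp.IntensityMatrix:
    """Small random lognormal intensity matrix with cohort labels."""
    if n_patients is None:
        n_patients = n_samples // 2
    values = pd.DataFrame(
        np.exp(rng.normal(0, 1, (n_samples, n_antigens))),
        index=[f"S{i}" for i in range(n_samples)],
        columns=[f"A{j}" for j in range(n_antigens)],
    )
    labels = pd.Series(
        ["patient"] * n_patients + ["control"] * (n_samples - n_patients),
        index=values.index,
        name="cohort",
    )
    return sp.IntensityMatrix(values, labels)
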