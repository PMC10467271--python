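import numpy as np
import pytest

import fnirsnet as fn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def schedule():
    return fn.generate_stimulus_schedule(seed=7)


@pytest.fixture(scope="session")
def short_schedule():
    """A 60-s task with a 20-s baseline, for fast forward-model tests."""
    return fn.generate_stimulus_schedule(task_duration_s=60, rest_duration_s=20, seed=7)


@pytest.fixture(scope="session")
def group_covariances():
    return {
        g: {s: fn.generate_group_covariance(g, s, effect_size=1.0) for s in ("rest", "task")}
        for g in ("PSD", "nonPSD")
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny HbO-stage cohort (4 vs 4) for pipeline-level tests."""
    return fn.generate_cohort(fn.CohortConfig(n_psd=4, n_nonpsd=4, emit_stage="hbo", seed=42))


@pytest.fixture(scope="session")
def intensity_subject(schedule, group_covariances):
    """One artifact-free raw-intensity subject with known ground truth."""
    return fn.generate_subject(
        "nonPSD", group_covariances["nonPSD"], schedule,
        artifact_params=fn.ArtifactParams.none(), seed=5,
    )


def random_adjacency(rng, n=None, p=None):
    """Random undirected simple graph as a boolean adjacency matrix."""
    n = n or int(rng.integers(8, 15))
    p = p if p is not None else rng.uniform(0.15, 0.7)
    a = rng.random((n, n)) < p
    a = np.triu(a, k=1)
    a = a | a.T
    return a
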