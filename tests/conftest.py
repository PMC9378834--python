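import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirpairs import CASE, CONTROL, ExpressionMatrix, LabelMap, SimConfig, generate_cohorts

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220802)


def make_matrix(values, mirna_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    mirna_ids = mirna_ids or [f"mir-{i}" for i in range(m)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n)]
    return ExpressionMatrix.from_arrays(mirna_ids, sample_ids, values)


def random_matrix(rng, m, n, prefix="") -> ExpressionMatrix:
    return make_matrix(
        rng.lognormal(mean=3.0, sigma=1.0, size=(m, n)),
        mirna_ids=[f"{prefix}mir-{i}" for i in range(m)],
        sample_ids=[f"{prefix}s{j}" for j in range(n)],
    )


def cohort_truth(cases: ExpressionMatrix, controls: ExpressionMatrix) -> LabelMap:
    labels = {sid: CASE for sid in cases.sample_ids}
    labels.update({sid: CONTROL for sid in controls.sample_ids})
    return LabelMap(labels)


@pytest.fixture(scope="session")
def recovery_cohorts():
    """The planted-recovery benchmark cohorts used across the suite (seed 1)."""
    return generate_cohorts(SimConfig(seed=1))
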