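import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cmapscreen.expression import CASE, CONTROL, ExpressionMatrix

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, probes, samples, n_case):
    """Expression matrix where the first n_case samples are cases."""
    labels = {
        s: (CASE if i < n_case else CONTROL) for i, s in enumerate(samples)
    }
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=probes, columns=samples),
        labels,
    )


@pytest.fixture
def small_matrix():
    """3 probes x 4 samples, 2 case / 2 control."""
    return make_matrix(
        [[1.0, 2.0, 3.0, 4.0], [5.5, 6.5, 7.5, 8.5], [0.25, 0.5, 0.75, 1.0]],
        probes=["pA", "pB", "pC"],
        samples=["s1", "s2", "s3", "s4"],
        n_case=2,
    )


@pytest.fixture(scope="session")
def default_cohort():
    from cmapscreen.synthetic import default_cohort_truth, make_cohort

    truth = default_cohort_truth(seed=1)
    matrix, truth = make_cohort(truth)
    return matrix, truth


@pytest.fixture(scope="session")
def default_signature(default_cohort):
    from cmapscreen.signature import select_signature

    matrix, _ = default_cohort
    return select_signature(matrix)
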