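import numpy as np
import pytest

from fsor import ClinicalTable, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_clinical():
    """Ten patients, mixed events and censoring, times in days."""
    return ClinicalTable(
        [f"P{i}" for i in range(10)],
        np.array([100.0, 250, 400, 90, 600, 330, 720, 150, 480, 60]),
        np.array([1, 0, 1, 1, 0, 1, 0, 1, 1, 1]),
    )


@pytest.fixture
def small_expression(small_clinical, rng):
    vals = rng.normal(7.0, 1.0, size=(4, 10))
    return ExpressionMatrix(
        vals, [f"G{i}" for i in range(4)], list(small_clinical.sample_ids)
    )


def random_stiefel(rng, d, k):
    q, _ = np.linalg.qr(rng.standard_normal((d, k)))
    return q[:, :k]


def random_psd(rng, d, scale=1.0):
    a = rng.standard_normal((d, d))
    return scale * (a @ a.T) / d
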