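import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deltapcc import ExpressionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(values, feature_prefix="F", sample_prefix="S", unit="TPM", classes=None):
    values = np.asarray(values, dtype=float)
    features = [f"{feature_prefix}{i:03d}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j:03d}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, features, samples, unit, classes)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_cohort(rng):
    """Small random expression pair (positive, non-degenerate) plus ids."""
    n_rna, n_mirna, n_samples = 6, 4, 12
    rna = make_matrix(np.exp(rng.standard_normal((n_rna, n_samples))), "RNA")
    mirna = make_matrix(np.exp(rng.standard_normal((n_mirna, n_samples))), "MIR", unit="CPM")
    normal_ids = rna.sample_ids[:8]
    tumour_ids = rna.sample_ids[8:]
    return rna, mirna, normal_ids, tumour_ids
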