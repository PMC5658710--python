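import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from superpca import ClinicalOutcome, ExpressionMatrix


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    """3 genes x 4 samples with easy-to-eyeball values."""
    values = np.array([[1.0, 2.0, 3.0, 4.0],
                       [0.5, 0.25, -1.0, 2.5],
                       [10.0, 9.0, 8.0, 7.0]])
    return ExpressionMatrix(["G1", "G2", "G3"], ["S1", "S2", "S3", "S4"], values)


@pytest.fixture
def survival_outcome() -> ClinicalOutcome:
    return ClinicalOutcome("survival", ["S1", "S2", "S3", "S4"],
                           time=np.array([5.0, 3.0, 8.0, 2.0]),
                           event=np.array([1, 0, 1, 1]))


def random_instance(seed: int, n_samples: int = 30, n_features: int = 20):
    """A random expression matrix plus all three outcome flavors."""
    rng = np.random.default_rng(seed)
    X = ExpressionMatrix(
        [f"G{j}" for j in range(n_features)],
        [f"S{i}" for i in range(n_samples)],
        rng.standard_normal((n_features, n_samples)),
    )
    surv = ClinicalOutcome("survival", X.sample_ids,
                           time=rng.exponential(1.0, n_samples) + 1e-3,
                           event=rng.integers(0, 2, n_samples))
    if surv.event.sum() == 0:
        surv.event[0] = 1
    cont = ClinicalOutcome("continuous", X.sample_ids,
                           value=rng.standard_normal(n_samples))
    label = rng.integers(0, 2, n_samples)
    while min(label.sum(), n_samples - label.sum()) < 2:
        label = rng.integers(0, 2, n_samples)
    binr = ClinicalOutcome("binary", X.sample_ids, label=label)
    return X, surv, cont, binr
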