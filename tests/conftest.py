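import numpy as np
import pandas as pd
import pytest

from cdrp.cohort import ClinicalTable, ExpressionMatrix
from cdrp.simulate import CohortConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    """20 samples × 10 genes, every gene Entrez-annotated."""
    values = rng.normal(5.0, 2.0, size=(20, 10))
    return ExpressionMatrix(
        values,
        [f"s{i}" for i in range(20)],
        [f"g{j}" for j in range(10)],
        [str(1000 + j) for j in range(10)],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Modest synthetic cohort shared by protocol-level tests."""
    cfg = CohortConfig(n_samples=250, n_genes=200, n_informative=40, seed=11)
    return generate(cfg)


@pytest.fixture
def tiny_clinical():
    return ClinicalTable(pd.DataFrame({
        "sample_id": ["a", "b", "c", "d"],
        "hr": [0, 1, 0, 1],
        "efs": [0, 1, 0, 1],
        "os": [0, 1, 0, 0],
        "efs_days": [100.0, 50.0, 200.0, 80.0],
        "os_days": [100.0, 60.0, 200.0, 90.0],
        "inss": ["1", "4", "2", "4"],
        "age_days": [200, 400, 300, 500],
        "gender": ["M", "F", "F", "M"],
        "country": ["A", "A", "B", "B"],
    }))
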