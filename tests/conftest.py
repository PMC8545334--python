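import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from proteoflow import ExpressionMatrix, SampleDesign

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 proteins x 4 samples with missing fractions {0, .25, .5, 1}."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, np.nan, np.nan],
            "s2": [1.5, 2.5, 3.0, np.nan],
            "s3": [0.5, np.nan, np.nan, np.nan],
            "s4": [1.0, 2.0, 3.5, np.nan],
        },
        index=["prot_full", "prot_q1", "prot_half", "prot_empty"],
    )
    return ExpressionMatrix(values=values)


@pytest.fixture
def two_group_design() -> SampleDesign:
    return SampleDesign(
        samples=["a1", "a2", "a3", "b1", "b2", "b3"],
        conditions=["A", "A", "A", "B", "B", "B"],
    )


@pytest.fixture
def paired_design() -> SampleDesign:
    return SampleDesign(
        samples=["a1", "a2", "a3", "b1", "b2", "b3"],
        conditions=["A", "A", "A", "B", "B", "B"],
        subjects=["s1", "s2", "s3", "s1", "s2", "s3"],
    )


def make_matrix(array, prefix="P", samples=None) -> ExpressionMatrix:
    """Helper: wrap a 2d array (proteins x samples) as an ExpressionMatrix."""
    array = np.asarray(array, dtype=float)
    index = [f"{prefix}{i:04d}" for i in range(array.shape[0])]
    cols = samples or [f"S{j}" for j in range(array.shape[1])]
    return ExpressionMatrix(values=pd.DataFrame(array, index=index, columns=cols))
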