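import numpy as np
import pytest

from tsnet.expression_io import ExpressionMatrix, SampleTable


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 2.0, 1.0],
            [5.0, 5.0, 6.0, 6.0],
        ]
    )
    return ExpressionMatrix(["P1", "P2", "P3"], ["s1", "s2", "s3", "s4"], values)


@pytest.fixture
def small_samples() -> SampleTable:
    return SampleTable(
        sample_ids=["s1", "s2", "s3", "s4"],
        condition=["normal", "normal", "tumor", "tumor"],
        stage=["unknown", "unknown", "2", "2"],
        subject_id=["pA", "pB", "pA", "pB"],
        smoking=["no", "unknown", "no", "unknown"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
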