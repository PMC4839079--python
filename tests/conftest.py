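import numpy as np
import pandas as pd
import pytest

from stagewise.design import ExperimentDesign, three_stage_design
from stagewise.matrix import CountMatrix, ExpressionMatrix


@pytest.fixture
def design9() -> ExperimentDesign:
    """Standard 3-stage x 3-replicate design (S1a..S3c)."""
    return three_stage_design(3)


@pytest.fixture
def design2() -> ExperimentDesign:
    return ExperimentDesign(
        samples=("A", "B"),
        stage_of={"A": "S1", "B": "S1"},
        stage_order=("S1",),
        transitions=(),
    )


@pytest.fixture
def toy_counts(design9) -> CountMatrix:
    rng = np.random.default_rng(7)
    frame = pd.DataFrame(
        rng.integers(0, 200, size=(20, 9)),
        index=[f"f{i}" for i in range(20)],
        columns=list(design9.samples),
    )
    return CountMatrix(frame, design9)


def random_counts(seed: int, n_features: int, design=None) -> CountMatrix:
    design = design or three_stage_design(3)
    rng = np.random.default_rng(seed)
    vals = rng.integers(0, 500, size=(n_features, len(design.samples)))
    vals[rng.random(vals.shape) < 0.15] = 0
    frame = pd.DataFrame(
        vals,
        index=[f"f{i}" for i in range(n_features)],
        columns=list(design.samples),
    )
    return CountMatrix(frame, design)


def expression_from(values, design=None) -> ExpressionMatrix:
    design = design or three_stage_design(3)
    frame = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"f{i}" for i in range(len(values))],
        columns=list(design.samples),
    )
    return ExpressionMatrix(frame, design)
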