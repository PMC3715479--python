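import numpy as np
import pandas as pd
import pytest

from crossde.preprocess import ExpressionMatrix, ProbeMatrix
from crossde.sam import SAMConfig


def make_expression(values: np.ndarray, groups: dict[str, int],
                    platform: str = "microarray") -> ExpressionMatrix:
    """Wrap a gene x sample array with sequential sample ids per group."""
    samples, labels = [], []
    for group, count in groups.items():
        for i in range(count):
            samples.append(f"{group}_{i}")
            labels.append(group)
    frame = pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples
    )
    return ExpressionMatrix(frame, platform=platform,
                            groups=pd.Series(labels, index=samples))


@pytest.fixture
def probe_matrix_with_missing():
    rng = np.random.default_rng(42)
    values = rng.normal(7, 1, size=(20, 10))
    frame = pd.DataFrame(
        values,
        index=[f"p{i}" for i in range(20)],
        columns=[f"s{i}" for i in range(10)],
    )
    frame.iloc[0, :3] = np.nan  # 30% missing
    frame.iloc[1, :2] = np.nan  # 20% missing
    frame.iloc[2, 0] = np.nan  # 10% missing
    return ProbeMatrix(frame)


@pytest.fixture
def quick_sam_config():
    return SAMConfig(seed=123, n_permutations=200, target_fdr=0.05,
                     s0_method="fixed_percentile")
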