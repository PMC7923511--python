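import numpy as np
import pytest
from hypothesis import settings

from cytopattern.io import BinaryMatrix, parse_feature_name

settings.register_profile("deterministic", derandomize=True, database=None,
                          deadline=None)
settings.load_profile("deterministic")


def make_matrix(values, sample_ids=None, raw_names=None, labels=None) -> BinaryMatrix:
    """Build a BinaryMatrix from a plain 0/1 array with generated names."""
    values = np.asarray(values)
    n, d = values.shape
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    if raw_names is None:
        codes = ["L", "G", "F"]
        raw_names = [f"{(j % 22) + 1}q{j // 22 + 1}.{codes[j % 3]}" for j in range(d)]
    features = [parse_feature_name(r, strict=False) for r in raw_names]
    return BinaryMatrix(sample_ids=sample_ids, features=features,
                        values=values, labels=labels)


@pytest.fixture
def toy_matrix() -> BinaryMatrix:
    """3 samples x 4 features with realistic LGF headers."""
    return make_matrix(
        [[1, 0, 1, 0], [0, 1, 1, 0], [1, 1, 0, 1]],
        raw_names=["8q24.F", "14q32.F", "13q14.L", "13q14.G"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
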