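import numpy as np
import pytest

from lossycode import DistortionMatrix, EnvironmentSpec, SourceDistribution, draw_matrix


@pytest.fixture
def hamming2() -> DistortionMatrix:
    """2x2 Hamming distortion: the binary source with closed form R(D) = 1 - H_b(D)."""
    return DistortionMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def uniform2() -> SourceDistribution:
    return SourceDistribution.uniform(2)


def random_matrix(n: int, seed: int, shift: float = 0.0, mean: float = 1.0) -> DistortionMatrix:
    """Small shifted-exponential draw used across solver tests."""
    return draw_matrix(
        EnvironmentSpec("exponential", shift, {"mean": mean}, n, seed)
    )


def binary_entropy_bits(p: float) -> float:
    if p in (0.0, 1.0):
        return 0.0
    return -p * np.log2(p) - (1 - p) * np.log2(1 - p)
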