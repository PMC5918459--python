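import numpy as np
import pytest

from fgmdr.glm_scores import ScoreVector
from fgmdr.io_formats import GenotypeMatrix


def random_instance(rng: np.random.Generator, n: int = 40, p: int = 4, missing_rate: float = 0.0):
    """Small random genotype matrix + score vector for oracle comparisons."""
    values = rng.integers(0, 3, size=(n, p)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n, p)) < missing_rate
        values[mask] = -1
    genos = GenotypeMatrix(
        samples=[f"I{i}" for i in range(n)],
        snps=[f"SNP{j + 1}" for j in range(p)],
        values=values,
    )
    scores = ScoreVector(s=rng.normal(0, 1, size=n), family="gaussian")
    return genos, scores


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
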