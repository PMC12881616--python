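import numpy as np
import pytest

from floquet_ews import UniformSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ar1():
    """Factory for AR(1) series with given per-step memory."""

    def make(phi: float, n: int, seed: int = 0, sd: float = 1.0) -> UniformSeries:
        g = np.random.default_rng(seed)
        x = np.empty(n)
        x[0] = g.standard_normal() * sd / np.sqrt(max(1.0 - phi * phi, 1e-12))
        eps = g.standard_normal(n) * sd
        for k in range(1, n):
            x[k] = phi * x[k - 1] + eps[k]
        return UniformSeries(np.arange(n, dtype=float), x)

    return make
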