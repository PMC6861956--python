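import numpy as np
import pytest

from owfb import DesignSpec, WaveletFilterBank, design_filter_bank

# (filter length, zero moments) pairs exercised throughout the suite
DESIGN_CASES = [(2, 1), (4, 2), (6, 2), (8, 3), (16, 4)]


@pytest.fixture(scope="session")
def banks() -> dict[tuple[int, int], WaveletFilterBank]:
    """Designed banks for every standard case, computed once per run."""
    return {
        (N, M): design_filter_bank(DesignSpec(N, M)) for N, M in DESIGN_CASES
    }


@pytest.fixture(scope="session")
def haar_bank(banks) -> WaveletFilterBank:
    return banks[(2, 1)]


@pytest.fixture(scope="session")
def default_bank(banks) -> WaveletFilterBank:
    """The N=16, M=4 default design used by the screening pipeline."""
    return banks[(16, 4)]


def fbm_midpoint(hurst: float, n_levels: int, seed: int) -> np.ndarray:
    """Fractional-Brownian-like trace by random midpoint displacement.

    Serves as the independent oracle for fractal-dimension estimates: the
    graph of such a trace has dimension ~ 2 - H.
    """
    rng = np.random.default_rng(seed)
    n = 2**n_levels
    x = np.zeros(n + 1)
    x[-1] = rng.standard_normal()
    step, sd = n, 1.0
    while step > 1:
        half = step // 2
        sd *= 2.0 ** (-hurst)
        for i in range(half, n, step):
            x[i] = 0.5 * (x[i - half] + x[i + half]) + sd * rng.standard_normal()
        step = half
    return x[:-1]
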