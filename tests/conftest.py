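import numpy as np
import pytest

import tigersim as ts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def vacuum_dimer():
    return ts.make_dimer_fixture(seed=1, n_solvent=0)


@pytest.fixture(scope="session")
def solvated_dimer():
    return ts.make_dimer_fixture(seed=1, n_solvent=50)


def blocked_sem(x, n_blocks: int = 40):
    """Standard error of the mean of a correlated series via batch means."""
    x = np.asarray(x, dtype=float)
    n = x.size // n_blocks
    if n < 1:
        raise ValueError("series too short for blocking")
    means = x[: n * n_blocks].reshape(n_blocks, n).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_blocks)


def exact_double_well_samples(barrier, asymmetry, temperature, n, seed=0):
    """Inverse-CDF samples from the 1D double-well Boltzmann density."""
    pot = ts.make_double_well(barrier, asymmetry).build()
    lo, hi = pot.bounds
    xs = np.linspace(lo, hi, 20001)
    w = np.exp(-pot.energy_grid(xs) / (ts.KB * temperature))
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) * 0.5 * np.diff(xs))])
    cdf /= cdf[-1]
    u = np.random.default_rng(seed).random(n)
    return np.interp(u, cdf, xs)
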