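import numpy as np
import pytest

from pclm import ModelConfig, PCLM, SimConfig, simulate_proteome
from pclm.types import MotifPWM


@pytest.fixture(scope="session")
def small_proteome():
    """A small simulated proteome shared across read-only tests."""
    cfg = SimConfig(n_proteins=30, length_range=(60, 140), seed=11)
    return simulate_proteome(cfg)


@pytest.fixture()
def toy_motifs():
    rng = np.random.default_rng(5)
    out = []
    for i, l in enumerate((3, 5)):
        M = rng.dirichlet(np.ones(20), size=l)
        out.append(MotifPWM(f"m{i}", M))
    return out


@pytest.fixture()
def tiny_model(toy_motifs):
    """A deliberately small model for gradient checks and unit tests."""
    cfg = ModelConfig(lstm_hidden=4, conv_channels=2, kernel_size=3,
                      d_stc=3, d_a=3, d_c=3, n_fused=4, window=3)
    return PCLM(cfg, toy_motifs, seed=7)


def finite_diff_grad(f, x, eps=1e-5):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        old = x[idx]
        x[idx] = old + eps
        fp = f()
        x[idx] = old - eps
        fm = f()
        x[idx] = old
        g[idx] = (fp - fm) / (2 * eps)
    return g


def rel_err(a, b):
    # the denominator floor keeps near-zero gradients (where the central
    # difference is dominated by cancellation noise) from swamping the ratio
    denom = np.maximum(np.abs(a) + np.abs(b), 1e-6)
    return np.max(np.abs(a - b) / denom)
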