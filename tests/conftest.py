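import numpy as np
import pytest

from pathbayes.hier_model import HyperParams, MarginalModel


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_model(rng):
    """8 individuals, 20 SNPs, 4 pathways; moderate prior variances."""
    G = rng.integers(0, 3, size=(8, 20)).astype(float)
    P = (rng.random((20, 4)) < 0.4).astype(np.int8)
    P[:, 0] = 0  # pathway 1 deliberately empty -> zero design column
    y = rng.standard_normal(8)
    hp = HyperParams(a=0.05, b=0.1, nu0=6.0, s0sq=1.2)
    return MarginalModel(y, G, P.astype(float), hp)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return str(path)
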