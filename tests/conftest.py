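import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

import einmol as em


@pytest.fixture(scope="session")
def small_fcc():
    """A 4-site fcc cell with a 5 Å lattice constant."""
    return em.build_fcc_crystal(1, 5.0)


@pytest.fixture(scope="session")
def fcc32():
    """The 32-atom (2×2×2 cells) crystal used by the heavier studies."""
    return em.build_fcc_crystal(2, 5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def gaussian_ladder_u(ks, n, rng):
    """(K, K·n) reduced potentials for 1-dof harmonic states sampled exactly.

    State k draws n points from N(0, 1/k_k); u[l] evaluates all pooled
    points under every state's Hamiltonian.  The exact free energy ladder
    is f_l − f_0 = ½·ln(k_l/k_0).
    """
    ks = np.asarray(ks, dtype=float)
    K = ks.size
    x = np.concatenate([rng.normal(0.0, 1.0 / np.sqrt(k), size=n) for k in ks])
    u = 0.5 * ks[:, None] * x[None, :] ** 2
    return u, np.full(K, n)
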