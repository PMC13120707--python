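import numpy as np
import pytest

import gwcrash as gw


@pytest.fixture(scope="session")
def lattice5():
    return gw.generate_lattice(5, 1.0, seed=0)


@pytest.fixture(scope="session")
def queen_w(lattice5):
    return gw.row_standardize(gw.contiguity_weights(lattice5, "queen"))


@pytest.fixture(scope="session")
def rook8_w():
    units = gw.generate_lattice(8, 1.0, seed=0)
    return units, gw.row_standardize(gw.contiguity_weights(units, "rook"))


@pytest.fixture(scope="session")
def gradient12():
    """Spatially varying NB study on a 12x12 lattice (144 zones)."""
    return gw.gradient_study(seed=1, n_side=12)


@pytest.fixture(scope="session")
def paper_like():
    """Overdispersed ~196-zone study emulating a national district table."""
    return gw.paper_like_study(seed=1)


@pytest.fixture(scope="session")
def constant5000():
    """Constant-coefficient NB counts, beta0 = ln 16, alpha = 1, ~5000 zones."""
    return gw.constant_study(seed=7, n_side=71)


def nb_logpmf_oracle(y, mu, alpha):
    """Independent NB2 log-pmf via scipy's nbinom parameterization.

    NB2 with mean mu and dispersion alpha corresponds to nbinom with
    size r = 1/alpha and success probability p = r / (r + mu).
    """
    from scipy import stats

    r = 1.0 / alpha
    return stats.nbinom.logpmf(y, r, r / (r + mu))
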