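import numpy as np
import pandas as pd
import pytest

import voxfluor as vf
from voxfluor.optics import OpticsTable


@pytest.fixture(scope="session")
def breast_phantom():
    """Default synthetic breast phantom, shared (read-only) across tests."""
    return vf.generate_breast_phantom(vf.PhantomParams(seed=1))


@pytest.fixture(scope="session")
def uniform_optics_factory():
    """Factory for homogeneous optics tables: every tissue gets the same
    (mu_a, mu_s, g, n) at every wavelength."""

    def make(mu_a, mu_s, g, n):
        frame = OpticsTable.default().frame.copy()
        frame["mu_a"] = mu_a
        frame["mu_s"] = mu_s
        frame["g"] = g
        frame["n"] = n
        return OpticsTable(frame)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
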