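import numpy as np
import pytest

import mlgmsim as m


@pytest.fixture(scope="session")
def spec():
    return m.default_spec()


@pytest.fixture(scope="session")
def basis(spec):
    return spec.basis


@pytest.fixture()
def tiny_dataset(spec):
    """Four clusters, sizes 2/2/6/6 — small enough for the brute-force oracle."""
    return m.simulate_dataset(spec, m.DesignCondition(4, 2, 6), seed=7)


@pytest.fixture(scope="session")
def fitted_catalog(spec):
    """One NG=200/GS=25/75 replication with the full template catalog fitted."""
    ds = m.simulate_dataset(spec, m.DesignCondition(200, 25, 75), seed=314)
    stats = m.sufficient_stats(ds)
    return ds, stats, m.fit_catalog(stats, spec.basis)
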