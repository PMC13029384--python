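import numpy as np
import pytest

import bsaqtl as b


@pytest.fixture(scope="session")
def ci_table_30():
    """Null CI band for 30+30 bulks over a depth grid bracketing ~100x."""
    return b.ci_table(30, range(60, 161, 10), replicates=100_000, seed=11)


@pytest.fixture(scope="session")
def null_sim():
    """Default-design simulation with no planted QTLs (2x50 Mb, 2000 sites)."""
    return b.simulate_population(b.SimConfig(seed=1))


@pytest.fixture(scope="session")
def qtl_sim():
    """Default-design simulation with one strong planted QTL."""
    cfg = b.SimConfig(planted_qtls=(("chr1", 25_000_000, 8.0),), seed=2)
    return b.simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
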