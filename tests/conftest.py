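import numpy as np
import pytest

import popkdic as pk

#: short chain schedule used throughout the tests; long enough for the
#: strongly differentiated simulated datasets the tests use.
SHORT = dict(burn_in=400, retained=150, thinning=2)


@pytest.fixture(scope="session")
def split2():
    """Two-deme star-split dataset (50 diploids/deme, 100 loci)."""
    table, summary = pk.simulate_dataset(
        pk.make_model("split", 2), pk.SimConfig(50, 100, seed=20260928)
    )
    labels = np.array([int(x) for x in table.population_labels])
    return table, labels, summary


@pytest.fixture(scope="session")
def chain2(split2):
    """One K=2 inbreeding-mode chain on the split dataset."""
    table, _, _ = split2
    cfg = pk.ChainConfig(K=2, seed=77, inbreeding_mode=True, **SHORT)
    return pk.run_chain(table, cfg)


@pytest.fixture(scope="session")
def chain3(split2):
    """An overfitted K=3 chain on the same data (for panel-level tests)."""
    table, _, _ = split2
    cfg = pk.ChainConfig(K=3, seed=78, inbreeding_mode=True, **SHORT)
    return pk.run_chain(table, cfg)
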