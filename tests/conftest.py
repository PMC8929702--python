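import numpy as np
import pytest

from contness.counts_io import SampleMeta
from contness.simulate import make_fixture_poolcount


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory):
    """Deterministic poolcount / gene / sample fixture files (seed 7)."""
    outdir = tmp_path_factory.mktemp("fixture")
    return make_fixture_poolcount(7, outdir)


@pytest.fixture(scope="session")
def nested_design_samples():
    """2 backgrounds x 3 environments x 4 replicates (24 samples)."""
    return [
        SampleMeta(f"{g}_{e}_r{r}", g, e, r)
        for g in ("WT", "lon")
        for e in ("control", "canavanine", "heat")
        for r in (1, 2, 3, 4)
    ]


@pytest.fixture(scope="session")
def saturated_design_60():
    """The benchmark 60-sample, 12-cell nested design matrix."""
    X = np.zeros((60, 12))
    X[:, 0] = 1.0
    cells = np.repeat(np.arange(12), 5)
    for j in range(1, 12):
        X[cells == j, j] = 1.0
    return X
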