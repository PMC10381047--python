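import numpy as np
import pytest

import pylphy
from pylphy.stdlib import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def rng():
    """Fresh deterministic generator per use site is preferred; this one is
    for tests that only need *some* randomness."""
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def rsva_dir(tmp_path_factory):
    """Directory containing the synthetic dated virus NEXUS fixture."""
    d = tmp_path_factory.mktemp("rsva")
    pylphy.synthdata.write_rsva_like_nexus(d / "rsva_synthetic.nex")
    return d


@pytest.fixture
def run_example(rsva_dir, monkeypatch):
    """Run a bundled example script; scripts that read the synthetic NEXUS
    are run from the fixture directory."""

    def run(name, seed=1):
        monkeypatch.chdir(rsva_dir)
        return pylphy.run_script(pylphy.example_source(name), seed=seed)

    return run


def mean_and_se(x):
    x = np.asarray(x, dtype=float)
    return x.mean(), x.std(ddof=1) / np.sqrt(x.size)
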