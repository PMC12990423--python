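import numpy as np
import pytest

from mobipipe.synth import build_scenario, default_scenario, electrode_layout


@pytest.fixture(scope="session")
def layout():
    return electrode_layout()


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small but complete synthetic study tree (built once per session)."""
    out = tmp_path_factory.mktemp("study") / "tree"
    spec = default_scenario(n_td=3, n_asd=3, n_blocks=1, n_trials=40, seed=11)
    build_scenario(spec, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
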