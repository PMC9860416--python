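import numpy as np
import pytest

from doseaccqa import GridGeometry, ImageGrid, make_ed_phantom, make_scenario, synth_session_dose


@pytest.fixture(scope="session")
def ed_phantom():
    """Reference electron-density phantom (CT + structures), built once."""
    return make_ed_phantom()


@pytest.fixture(scope="session")
def ed_dose(ed_phantom):
    """Noise-free conformal session dose on the reference ED phantom."""
    _, structures = ed_phantom
    return synth_session_dose(structures, noise_sd=0.0)


@pytest.fixture(scope="session")
def swap_bundle():
    """One 2-fraction insert-swap scenario shared across tests."""
    return make_scenario("insert_swap", n_fractions=2, seed=11)


@pytest.fixture(scope="session")
def control_bundle():
    return make_scenario("pelvis_control", n_fractions=2, seed=7)


@pytest.fixture
def random_grid():
    def _make(seed=0, shape=(10, 10, 10), spacing=(2.0, 2.0, 2.0), lo=0.0, hi=100.0):
        rng = np.random.default_rng(seed)
        return ImageGrid(rng.uniform(lo, hi, shape), (0.0, 0.0, 0.0), spacing)

    return _make
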