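import numpy as np
import pytest

from phototox.synthetic import SyntheticScenario, render_video


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """A compact control-like scenario shared across tests."""
    return SyntheticScenario(
        n_cells=25, field_shape=(256, 256), duration=200.0, seed=1
    )


@pytest.fixture(scope="session")
def small_render(small_scenario):
    """(video, truth) for the shared scenario; rendered once per session."""
    return render_video(small_scenario)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
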