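import numpy as np
import pytest

from bacmotil import synth
from bacmotil.trajectory import Trajectory


@pytest.fixture(scope="session")
def noiseless_scene():
    return synth.SceneParams(noise_sigma=0.0)


@pytest.fixture(scope="session")
def stationary_spot_traj():
    """300-frame stationary spot at (42.3, 38.7) px in a 0.26 µm/px scene."""
    t = np.arange(300) / 500.0
    x = np.full(300, 42.3 * 0.26)
    y = np.full(300, 38.7 * 0.26)
    beta = np.full(300, 40.0)
    return Trajectory(t, x, y, beta=beta)


@pytest.fixture(scope="session")
def noiseless_stack(stationary_spot_traj, noiseless_scene):
    return synth.render_video([stationary_spot_traj], [synth.SpotAppearance()],
                              noiseless_scene, seed=0)


@pytest.fixture(scope="session")
def noisy_stack(stationary_spot_traj):
    """SNR 10: spot amplitude 2000 over Gaussian noise of σ = 200 counts."""
    scene = synth.SceneParams(noise_sigma=200.0)
    return synth.render_video([stationary_spot_traj], [synth.SpotAppearance()],
                              scene, seed=1)
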