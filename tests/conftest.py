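import numpy as np
import pytest

from acuheight.signal_model import ChirpConfig, SpeakerArray
from acuheight.scene_sim import AcousticScene, Trajectory, render_received


@pytest.fixture(scope="session")
def cfg() -> ChirpConfig:
    return ChirpConfig()


@pytest.fixture(scope="session")
def array() -> SpeakerArray:
    return SpeakerArray(L=0.1)


@pytest.fixture(scope="session")
def static_render(cfg, array):
    """Noiseless drift-free static scene at 1 m, shared across tests."""
    scene = AcousticScene(
        array=array, cfg=cfg, trajectory=Trajectory.static([0.0, 0.0, 1.0])
    )
    return scene, render_received(scene, 3.0, seed=11)


def synth_frame(cfg, delays_s, amps=None, speakers=(0, 1, 2)):
    """Directly synthesized single received frame: sum of delayed chirps."""
    from acuheight.signal_model import chirp_phase

    t = np.arange(cfg.n_samples) / cfg.fs
    if amps is None:
        amps = [1.0] * len(delays_s)
    y = np.zeros(cfg.n_samples)
    for i, tau, a in zip(speakers, delays_s, amps):
        y += a * np.cos(chirp_phase(t - tau, cfg, i))
    return y
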