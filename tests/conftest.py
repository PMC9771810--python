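import numpy as np
import pytest

import marshchange as mc


@pytest.fixture(scope="session")
def clean_scene():
    """Zero-noise, zero-dropout scene with one event of each kind."""
    cfg = mc.SceneConfig(height=48, width=48, noise_sd=0.0, dropout=0.0, seed=7)
    cfg.events = [
        mc.ChangeEvent(pixels=((12, 12), (12, 13), (13, 12)), kind="loss",
                       onset_epoch=1, delta=0.3),
        mc.ChangeEvent(pixels=((20, 20), (20, 21)), kind="gain",
                       onset_epoch=2, delta=0.3),
        mc.ChangeEvent(pixels=((30, 30),), kind="recovery",
                       onset_epoch=0, delta=0.3, recovery_epoch=2),
    ]
    return mc.generate_scene(cfg)


@pytest.fixture(scope="session")
def clean_change(clean_scene):
    return mc.compute_change_map(clean_scene.stack, clean_scene.config.epochs,
                                 clean_scene.reference)
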