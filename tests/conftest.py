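import numpy as np
import pytest

import gastrolayer as gl


@pytest.fixture(scope="session")
def flat_noise_free():
    """Flat five-band phantom without speckle (template == image)."""
    return gl.generate_phantom(gl.PhantomSpec(speckle_looks=None))


@pytest.fixture(scope="session")
def speckled_phantom():
    """Default phantom with 4-look speckle, fixed seed."""
    return gl.generate_phantom(gl.PhantomSpec(speckle_looks=4, seed=7))


@pytest.fixture(scope="session")
def curved_phantom():
    return gl.generate_phantom(gl.PhantomSpec(curvature=20, speckle_looks=None))


@pytest.fixture(scope="session")
def trained_small_detector():
    """A tiny U-net trained on six 64x64 flat phantoms (shared across tests)."""
    from gastrolayer.detect import DetectorConfig, train_detector

    cohort = [
        gl.generate_phantom(
            gl.PhantomSpec(height=64, width=64, wall_top_row=12 + (i % 3) * 4,
                           wall_thickness=28 + 2 * (i % 3), seed=i)
        )
        for i in range(6)
    ]
    cfg = DetectorConfig(input_size=(64, 64), base_channels=4, epochs=20, seed=0)
    log: list[float] = []
    model = train_detector([c.image for c in cohort], [c.wall_mask for c in cohort],
                           cfg, log=log)
    return model, cohort, log
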