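"""Shared fixtures: small, fast phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from xasurrogate.phantom import PhantomConfig, PhantomScene, generate


def small_config(**overrides) -> PhantomConfig:
    """A 256x256, 60-frame phantom: same physics, quarter the area.

    The 256-pixel side keeps the auto downsampling factor at 4 (64x64
    grid), so preprocessing behaves as on clinical-size frames while unit
    tests stay fast.
    """
    params = dict(
        height=256,
        width=256,
        n_frames=60,
        breathing_amplitude_px=15.0,
        cardiac_amplitude_px=8.0,
        diaphragm_apex_x=160.0,
        diaphragm_apex_y=165.0,
        diaphragm_curvature=0.0016,
        vessel_width_px=8.0,
        catheter_width_px=5.0,
        fade_start_frame=30,
        seed=5,
    )
    params.update(overrides)
    return PhantomConfig(**params)


@pytest.fixture(scope="session")
def small_phantom() -> PhantomScene:
    return generate(small_config())


@pytest.fixture(scope="session")
def vessel_free_phantom() -> PhantomScene:
    return generate(
        small_config(n_vessel_branches=0, catheter=False, seed=11)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
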