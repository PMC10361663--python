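"""Shared fixtures: small simulated stacks reused across test modules."""

import numpy as np
import pytest

from spindleflux.synthetic import SimulationConfig, frap_preset, simulate


def bleach_half_mask(cfg: SimulationConfig, side: str = "left") -> np.ndarray:
    """Pixel mask of one image half, matching a half-spindle bleach."""
    ny, nx = cfg.image_shape
    mask = np.zeros((ny, nx), bool)
    if side == "left":
        mask[:, : nx // 2] = True
    else:
        mask[:, nx // 2 :] = True
    return mask


@pytest.fixture(scope="session")
def small_frap_run():
    """A quick half-spindle FRAP simulation (reduced molecule count)."""
    cfg = frap_preset(seed=11, n_molecules=6000)
    stack, truth = simulate(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def quiet_config():
    """Tiny noise-free configuration for deterministic rendering checks."""
    return SimulationConfig(
        n_molecules=50, n_frames=3, frame_interval=1.0, dt_sim=0.1,
        k_on_base=0.5, k_off=0.1, flux_velocity=0.0,
        shot_noise=False, read_noise_sd=0.0, background_level=5.0,
        rng_seed=7,
    )
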