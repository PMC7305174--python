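"""Shared fixtures: comb pairs and scenes at the three problem scales."""

import numpy as np
import pytest

from dcpas.comb import build_comb_pair
from dcpas.config import build_scene, make_fixture


@pytest.fixture(scope="session")
def paper_pair():
    """160 MHz combs, delta_f_rep = 66.81 Hz, 15 THz band at the standard anchor."""
    return build_comb_pair(160e6, 66.81, 171.2e12, 15e12)


def scene_for(name: str, scale: str, noise: float = 0.0, seed: int = 0, **mods):
    cfg = make_fixture(name, scale=scale)
    cfg.chain.noise_density_V = noise
    cfg.simulation.seed = seed
    for key, val in mods.items():
        block, field = key.split("__")
        setattr(getattr(cfg, block), field, val)
    return build_scene(cfg)


@pytest.fixture()
def reduced_vacnt_scene():
    """Noiseless reduced-scale flat-absorber scene (~450-sample records)."""
    return scene_for("vacnt", "reduced")


@pytest.fixture()
def demo_vacnt_noisy():
    """Demo-scale flat-absorber scene with single-shot SNR ~7."""
    return scene_for("vacnt", "demo", noise=6e-3)


@pytest.fixture(autouse=True)
def _fixed_numpy_seed():
    # legacy-global safety net; the package itself only uses Generator objects
    np.random.seed(1234)
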