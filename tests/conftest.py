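import numpy as np
import pytest

from octfoci import DetectionConfig, PhantomConfig, generate_volume


def flat_config(**overrides) -> PhantomConfig:
    """A geometrically trivial phantom: flat surfaces, constant thickness 100."""
    base = dict(
        curvature_px=0.0, fovea_dip_px=0.0, fovea_thinning=0.0,
        thickness_var_px=0.0, n_drusen=0, n_vessels=0, speckle_sigma=0.0,
    )
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture
def clean_config() -> PhantomConfig:
    """Default anatomy, no confounders, no noise."""
    return PhantomConfig(n_drusen=0, n_vessels=0, speckle_sigma=0.0, seed=1)


@pytest.fixture
def clean_phantom(clean_config):
    cfg = PhantomConfig(
        n_drusen=0, n_vessels=0, speckle_sigma=0.0, seed=1,
        foci_per_slab={1: 2, 2: 3, 3: 1},
    )
    vol, surf, ledger = generate_volume(cfg)
    return cfg, vol, surf, ledger


@pytest.fixture
def clean_detection() -> DetectionConfig:
    """Detection config for confounder-free phantoms (no auto-masking)."""
    return DetectionConfig(auto_vessel_mask=False, auto_drusen_mask=False)
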