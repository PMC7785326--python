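"""Shared fixtures: small synthetic datasets and reduced-scale configs.

Everything is generated programmatically at test time; fixtures are
session-scoped where regeneration would dominate runtime.
"""

import numpy as np
import pytest

from stackseg import (
    AugmentParams,
    ModelConfig,
    SimulationConfig,
    generate_dataset,
    render_hyperstack,
    scaled_config,
)
from stackseg.training import TrainConfig


@pytest.fixture(scope="session")
def sim_config_64() -> SimulationConfig:
    return scaled_config(64, seed=101)


@pytest.fixture(scope="session")
def positive_stack(sim_config_64):
    """One cell-bearing 10-channel hyper-stack with its mask."""
    from dataclasses import replace

    cfg = replace(sim_config_64, negative_fraction=0.0)
    stack, mask, meta = render_hyperstack(cfg, np.random.default_rng(7))
    return stack, mask


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A 10-image 64 px dataset on disk (8 positive, ~2 negative)."""
    out = tmp_path_factory.mktemp("tiny_dataset")
    cfg = scaled_config(64, negative_fraction=0.2, seed=42)
    manifest = generate_dataset(cfg, 10, out)
    return manifest


@pytest.fixture(scope="session")
def tiny_model_config() -> ModelConfig:
    """Reduced width and depth: CPU-scale but the full topology pattern."""
    return ModelConfig(width_multiplier=0.125, blocks_per_stage=(1, 1, 1, 1))


@pytest.fixture
def no_aug_64() -> AugmentParams:
    return AugmentParams(
        enable_dihedral=False, enable_rotation=False, enable_skew=False,
        enable_perspective=False, enable_jitter=False,
        enable_photometric=False, target_size=64)


@pytest.fixture
def smoke_train_config(no_aug_64) -> TrainConfig:
    """Memorization-scale training config (tiny, fast, deterministic)."""
    return TrainConfig(frozen_epochs=1, unfrozen_epochs=49, batch_size=2,
                       max_lr_phase1=1e-3, lr_range_phase2=(1e-3, 3e-3),
                       augment=no_aug_64, run_seed=0, split_seed=0)
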