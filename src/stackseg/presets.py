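"""Reusable experiment presets.

``desk_scale_protocol`` is the package's reference configuration for
CPU-scale reproductions of the strategy-comparison and robustness
protocols: 96 px synthetic fields, training inputs standardized to
64 px, a width-0.125 single-block-per-stage network, and a short
two-phase 1-cycle regimen with gradient clipping and precise-BN
refresh.  The structure (two phases, discriminative LRs, augmentation,
paired splits) mirrors the full-scale regimen; only the sizes differ.
"""

from __future__ import annotations

from .augmentation import AugmentParams
from .model import ModelConfig
from .synthetic import SimulationConfig, scaled_config
from .training import TrainConfig


def desk_scale_sim_config(image_size: int = 96, seed: int = 5,
                          **overrides) -> SimulationConfig:
    return scaled_config(image_size, seed=seed, **overrides)


def desk_scale_model_config(**overrides) -> ModelConfig:
    kwargs = dict(width_multiplier=0.125, blocks_per_stage=(1, 1, 1, 1))
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def desk_scale_augment(target_size: int = 64) -> AugmentParams:
    # gentler warps than the full-scale defaults: at 64 px, large
    # rotations and perspective distortions destroy thin membrane rims
    return AugmentParams(target_size=target_size, rotation_deg=30.0,
                         warp_magnitude=0.1)


def desk_scale_train_config(**overrides) -> TrainConfig:
    kwargs = dict(
        frozen_epochs=1,
        unfrozen_epochs=31,
        batch_size=10,
        max_lr_phase1=1.5e-3,
        lr_range_phase2=(8e-4, 2e-3),
        grad_clip=2.0,
        augment=desk_scale_augment(),
    )
    kwargs.update(overrides)
    return TrainConfig(**kwargs)
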