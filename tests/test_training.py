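"""Loss, splitting, schedules, the LR finder, and the training loop."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from stackseg.loading_codes import builtin_codes
from stackseg.model import build_model
from stackseg.stack_io import DatasetManifest
from stackseg.training import (
    ClassWeights,
    StackDataset,
    TrainConfig,
    group_peak_lrs,
    lr_ramp,
    lr_scan,
    one_cycle_schedule,
    split_dataset,
    suggest_lr,
    train,
    weighted_cross_entropy,
    _load_val_sample,
)


def reference_weighted_ce(logits, target, w_bg, w_cell):
    """Independent per-pixel evaluation of the loss formula."""
    total, wsum = 0.0, 0.0
    H, W = target.shape
    for i in range(H):
        for j in range(W):
            cls = int(target[i, j])
            w = w_cell if cls == 1 else w_bg
            x = [float(logits[0, i, j]), float(logits[1, i, j])]
            lse = math.log(math.exp(x[0]) + math.exp(x[1]))
            total += w * (-x[cls] + lse)
            wsum += w
    return total / wsum


class TestWeightedCrossEntropy:
    def test_symmetric_single_pixel_is_ln2(self):
        logits = np.zeros((2, 1, 1))
        target = np.ones((1, 1), dtype=np.uint8)
        loss = weighted_cross_entropy(logits, target, ClassWeights(1.0, 1.0))
        assert abs(loss - math.log(2.0)) < 1e-12

    def test_weighted_background_pixel_closed_form(self):
        # logits (background -1, cell 2), true class background, weight 0.5
        logits = np.array([-1.0, 2.0]).reshape(2, 1, 1)
        target = np.zeros((1, 1), dtype=np.uint8)
        per_pixel = weighted_cross_entropy(logits, target,
                                           ClassWeights(1.0, 0.5),
                                           reduction="none")
        expected = 0.5 * (1.0 + math.log(math.exp(2.0) + math.exp(-1.0)))
        assert abs(per_pixel.item() - expected) < 1e-12
        assert abs(per_pixel.item() - 1.52429) < 1e-4
        # the weighted mean normalizes the weight back out for one pixel
        mean_loss = weighted_cross_entropy(logits, target, ClassWeights(1.0, 0.5))
        assert abs(mean_loss - expected / 0.5) < 1e-12

    def test_matches_independent_oracle_on_random_batches(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            logits = rng.standard_normal((2, 5, 5)) * 3
            target = (rng.random((5, 5)) > 0.5).astype(np.uint8)
            w_bg, w_cell = rng.uniform(0.2, 2.0, size=2)
            ours = weighted_cross_entropy(logits, target,
                                          ClassWeights(w_cell, w_bg))
            ref = reference_weighted_ce(logits, target, w_bg, w_cell)
            assert abs(ours - ref) <= 1e-6 * abs(ref)

    def test_loss_vanishes_with_growing_margin(self):
        target = np.ones((1, 1), dtype=np.uint8)
        losses = []
        for margin in (1.0, 5.0, 20.0):
            logits = np.array([-margin, margin]).reshape(2, 1, 1)
            losses.append(weighted_cross_entropy(logits, target, ClassWeights()))
        assert losses[0] > losses[1] > losses[2]
        assert losses[2] < 1e-8

    def test_numerical_stability_at_large_logits(self):
        logits = np.array([1000.0, -1000.0]).reshape(2, 1, 1)
        target = np.zeros((1, 1), dtype=np.uint8)
        loss = weighted_cross_entropy(logits, target, ClassWeights())
        assert math.isfinite(loss) and loss < 1e-8

    def test_non_binary_target_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.zeros((2, 2, 2)),
                                   np.full((2, 2), 2), ClassWeights())

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((1, 2, 3, 3))
        target = (rng.random((1, 3, 3)) > 0.5).astype(np.uint8)
        w = ClassWeights(1.0, 0.5)
        _, grad = weighted_cross_entropy(logits, target, w, return_grad=True)
        eps = 1e-6
        for idx in np.ndindex(logits.shape):
            logits[idx] += eps
            up = weighted_cross_entropy(logits, target, w)
            logits[idx] -= 2 * eps
            dn = weighted_cross_entropy(logits, target, w)
            logits[idx] += eps
            assert abs(grad[idx] - (up - dn) / (2 * eps)) < 1e-6


def _fake_manifest(n):
    frame = pd.DataFrame({
        "image_path": [f"i{k}.tiff" for k in range(n)],
        "mask_path": [f"m{k}.png" for k in range(n)],
        "is_negative": [False] * n,
        "cell_type_tag": ["x"] * n,
        "markers_present": ["cyto"] * n,
    })
    return DatasetManifest(frame=frame)


class TestSplit:
    def test_eighty_twenty_of_275_is_220_55(self):
        tr, va = split_dataset(_fake_manifest(275), 0.8, split_seed=3)
        assert (len(tr), len(va)) == (220, 55)

    def test_partition_is_disjoint_and_exhaustive(self):
        man = _fake_manifest(40)
        tr, va = split_dataset(man, 0.8, split_seed=1)
        names = set(tr.frame.image_path) | set(va.frame.image_path)
        assert len(names) == 40
        assert not set(tr.frame.image_path) & set(va.frame.image_path)

    def test_same_seed_reproduces_split(self):
        man = _fake_manifest(50)
        a = split_dataset(man, 0.8, split_seed=9)
        b = split_dataset(man, 0.8, split_seed=9)
        assert a[0].frame.equals(b[0].frame)
        assert a[1].frame.equals(b[1].frame)

    def test_different_seeds_differ(self):
        man = _fake_manifest(275)
        a = split_dataset(man, 0.8, split_seed=1)
        b = split_dataset(man, 0.8, split_seed=2)
        assert not a[1].frame.equals(b[1].frame)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_fake_manifest(3), 0.999, split_seed=0)


class TestSchedules:
    def test_peak_equals_max_lr_exactly(self):
        for max_lr in (2e-4, 1e-3):
            lrs = one_cycle_schedule(max_lr, 100)
            assert lrs.max() == max_lr

    def test_single_peak_shape(self):
        lrs = one_cycle_schedule(1e-3, 60, warmup_frac=0.5)
        peak = int(np.argmax(lrs))
        assert (np.diff(lrs[:peak + 1]) >= 0).all()
        assert (np.diff(lrs[peak:]) <= 0).all()

    def test_endpoints_follow_divisors(self):
        lrs = one_cycle_schedule(1e-2, 50, div=25.0, final_div=1e4)
        assert abs(lrs[0] - 1e-2 / 25) < 1e-12
        assert abs(lrs[-1] - 1e-2 / 1e4) < 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_cycle_schedule(-1e-3, 10)
        with pytest.raises(ValueError):
            one_cycle_schedule(1e-3, 1)

    def test_group_lrs_geometric_between_endpoints(self):
        """Phase-2 peaks span [2e-6, 1e-4] with geometric spacing."""
        low, high = 2e-6, 1e-4
        peaks = group_peak_lrs(low, high, 3)
        assert peaks[0] == low
        assert abs(peaks[-1] - high) < 1e-18
        ratio = (high / low) ** 0.5
        np.testing.assert_allclose(peaks[1] / peaks[0], ratio, rtol=1e-12)
        np.testing.assert_allclose(peaks[2] / peaks[1], ratio, rtol=1e-12)


class TestLrFinder:
    def test_ramp_endpoints_and_geometric_spacing(self):
        lrs = lr_ramp(1e-7, 1e-1, 100)
        assert lrs[0] == 1e-7
        assert abs(lrs[-1] - 1e-1) < 1e-12
        ratios = lrs[1:] / lrs[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_quadratic_proxy_suggestion_in_stable_band(self):
        """Gradient descent on 0.5*lam*w^2: stable iff lr < 2/lam; the
        suggested lr should sit in the fast-and-stable band."""
        lam = 50.0
        w = np.array([1.0])

        def step(lr):
            loss = 0.5 * lam * float(w[0] ** 2)
            w[0] -= lr * lam * w[0]
            return loss

        records = lr_scan(step, lr_ramp(1e-5, 1.0, 200), smooth_beta=0.9)
        suggestion = suggest_lr(records)
        assert suggestion is not None
        assert 0.01 / lam < suggestion < 2.0 / lam

    def test_divergence_aborts_scan(self):
        lam = 50.0
        w = np.array([1.0])

        def step(lr):
            loss = 0.5 * lam * float(w[0] ** 2)
            w[0] -= lr * lam * w[0]
            return loss

        records = lr_scan(step, lr_ramp(1e-5, 10.0, 300), smooth_beta=0.9)
        assert len(records) < 300  # aborted before the ramp ended
        assert records[-1][0] > 2.0 / lam  # after instability set in

    def test_flat_loss_yields_no_suggestion(self):
        records = lr_scan(lambda lr: 1.0, lr_ramp(1e-6, 1e-2, 50))
        assert suggest_lr(records) is None

    def test_lr_find_on_model_warns_when_flat(self, tiny_dataset,
                                              tiny_model_config, no_aug_64):
        from stackseg.training import lr_find

        config = TrainConfig(batch_size=2, augment=no_aug_64)
        data = StackDataset(tiny_dataset.subset(range(2)))
        model = build_model(tiny_model_config, seed=0)
        # freeze everything: zero effective updates, loss cannot fall
        model.set_trainable(False)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            records, suggestion = lr_find(model, data,
                                          builtin_codes()["cytoplasm"],
                                          config, n_iters=12)
        assert suggestion is None
        assert any("no suggestion" in str(w.message) for w in caught)
        assert len(records) == 12


class TestTrainLoop:
    def test_default_regimen_is_105_epochs(self):
        cfg = TrainConfig()
        assert cfg.total_epochs == 105
        assert cfg.frozen_epochs == 5
        assert cfg.max_lr_phase1 == 2e-4
        assert cfg.lr_range_phase2 == (2e-6, 1e-4)

    @pytest.fixture()
    def tiny_run(self, tiny_dataset, tiny_model_config, no_aug_64):
        def run(run_seed=0, split_seed=0, epochs=(1, 2)):
            cfg = TrainConfig(frozen_epochs=epochs[0], unfrozen_epochs=epochs[1],
                              batch_size=4, max_lr_phase1=1e-3,
                              lr_range_phase2=(1e-3, 2e-3), augment=no_aug_64,
                              run_seed=run_seed, split_seed=split_seed)
            model = build_model(tiny_model_config, seed=run_seed)
            return train(model, tiny_dataset, cfg, builtin_codes()["cytoplasm"])
        return run

    def test_history_lengths_match_epochs(self, tiny_run):
        model, hist = tiny_run()
        assert len(hist.train_loss) == 3
        assert len(hist.val_accuracy) == 3
        assert len(hist.lr_trace) == 3 * 2  # 8 train images, batch 4

    def test_identical_seeds_reproduce_history(self, tiny_run):
        _, a = tiny_run(run_seed=5)
        _, b = tiny_run(run_seed=5)
        assert a.train_loss == b.train_loss
        assert a.val_accuracy == b.val_accuracy
        assert a.lr_trace == b.lr_trace

    def test_encoder_bit_identical_across_frozen_phase(
            self, tiny_dataset, tiny_model_config, no_aug_64):
        cfg = TrainConfig(frozen_epochs=2, unfrozen_epochs=0, batch_size=4,
                          max_lr_phase1=1e-3, augment=no_aug_64)
        model = build_model(tiny_model_config, seed=1)
        before = [p.data.tobytes() for p in model.encoder.parameters()]
        model, _ = train(model, tiny_dataset, cfg, builtin_codes()["cytoplasm"])
        after = [p.data.tobytes() for p in model.encoder.parameters()]
        assert before == after

    def test_validation_dropout_override_blanks_input(self, tiny_dataset):
        data = StackDataset(tiny_dataset)
        cfg = TrainConfig(val_dropout_override=1.0, val_dropout_param="channel",
                          augment=__import__("stackseg").AugmentParams(target_size=64))
        img, _ = _load_val_sample(data, 0, builtin_codes()["fluorescence"],
                                  cfg, epoch=0)
        assert img.max() == 0.0
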