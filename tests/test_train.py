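"""Training loop behaviour at desk scale: learning happens, determinism,
frozen-backbone staging, checkpoint round-trips, evaluation and prediction."""

import numpy as np
import pytest

from semd import (SEMD, SEMDConfig, SegDataset, TrainConfig, evaluate,
                  load_checkpoint, predict_files, save_checkpoint, train)
from semd.data import write_image
from semd.metrics import miou


def quick_cfg(**kw):
    base = dict(epochs=4, batch_size=4, lr=1e-3, input_size=32, seed=3,
                num_classes=2, augment=False)
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def small_dataset(tmp_path_factory):
    from semd import generate_dataset
    root = tmp_path_factory.mktemp("train_ds")
    generate_dataset(3, 32, 21, root)
    return root


def test_training_reduces_loss(small_dataset):
    _, run = train(small_dataset, quick_cfg(epochs=6))
    assert run.epochs[-1]["train_loss"] < run.epochs[0]["train_loss"]
    assert run.best_val_miou > 0.0
    assert run.wall_seconds > 0


def test_training_is_deterministic(small_dataset):
    _, run_a = train(small_dataset, quick_cfg())
    _, run_b = train(small_dataset, quick_cfg())
    assert run_a.train_losses == run_b.train_losses
    assert [e.get("val_miou") for e in run_a.epochs] == \
           [e.get("val_miou") for e in run_b.epochs]


def test_zero_learning_rate_freezes_loss(small_dataset):
    # one full batch per epoch so batch statistics are identical across epochs
    _, run = train(small_dataset, quick_cfg(lr=0.0, epochs=3, batch_size=16))
    losses = run.train_losses
    # constant up to float32 summation order (samples shuffle within the batch)
    assert max(losses) - min(losses) < 1e-4


def test_frozen_backbone_stage_leaves_backbone_unchanged(small_dataset):
    cfg = quick_cfg(epochs=2, freeze_backbone_epochs=2)
    model = SEMD(SEMDConfig(num_classes=2, output_stride=16, input_size=32),
                 rng=np.random.default_rng(cfg.seed))
    before = {k: v.copy() for k, v in model.backbone.state_dict().items()
              if "running" not in k}
    model, _ = train(small_dataset, cfg, model=model)
    after = model.backbone.state_dict()
    for k, v in before.items():
        np.testing.assert_array_equal(after[k], v)


def test_empty_dataset_raises(tmp_path):
    with pytest.raises((FileNotFoundError, ValueError)):
        train(tmp_path, quick_cfg())


def test_checkpoint_round_trip_reproduces_metrics(small_dataset, tmp_path):
    model, _ = train(small_dataset, quick_cfg(epochs=2))
    reports = evaluate(model, small_dataset, sizes=(32,))
    ckpt = tmp_path / "model.npz"
    save_checkpoint(model, ckpt)
    reloaded, _ = load_checkpoint(ckpt)
    reports2 = evaluate(reloaded, small_dataset, sizes=(32,))
    assert reports[32]["miou"] == reports2[32]["miou"]
    assert reports[32]["per_class_iou"] == reports2[32]["per_class_iou"]


def test_evaluate_oracle_predictions_score_one(small_dataset):
    class Oracle:
        cfg = SEMDConfig(num_classes=2)

        def __init__(self, masks):
            self.masks = masks
            self.i = 0

        def predict(self, images):
            n = len(images)
            out = np.stack(self.masks[self.i:self.i + n])
            self.i += n
            return out

    val = SegDataset(small_dataset, "val")
    masks = [s.mask.astype(np.uint8) for s in val.samples()]
    reports = evaluate(Oracle(masks), small_dataset, sizes=(32,))
    assert reports[32]["miou"] == pytest.approx(1.0)
    assert reports[32]["mpa"] == pytest.approx(1.0)
    assert reports[32]["psnr"] is not None


def test_evaluate_multiple_sizes_schema(small_dataset):
    model = SEMD(SEMDConfig(num_classes=2, input_size=32),
                 rng=np.random.default_rng(0))
    reports = evaluate(model, small_dataset, sizes=(32, 48))
    for size in (32, 48):
        report = reports[size]
        assert {"miou", "mpa", "per_class_iou", "psnr",
                "seconds_per_image", "n_images"} <= set(report)
        assert 0.0 <= report["miou"] <= 1.0


def test_predict_files_writes_mask_and_overlay(small_dataset, tmp_path, rng):
    model = SEMD(SEMDConfig(num_classes=2, input_size=32),
                 rng=np.random.default_rng(0))
    img_path = tmp_path / "scene.png"
    write_image(rng.integers(0, 255, (32, 32, 3)).astype(np.uint8), img_path)
    warnings = []
    written = predict_files(model, [img_path, tmp_path / "missing.png"],
                            tmp_path / "out", log_fn=warnings.append)
    assert len(written) == 2
    assert (tmp_path / "out" / "scene_mask.png").exists()
    assert (tmp_path / "out" / "scene_overlay.png").exists()
    assert any("missing.png" in w for w in warnings)


def test_run_log_serialization_round_trip(small_dataset, tmp_path):
    _, run = train(small_dataset, quick_cfg(epochs=2))
    path = tmp_path / "run.json"
    run.save(path)
    from semd import RunLog
    loaded = RunLog.load(path)
    assert loaded.train_losses == run.train_losses
    assert loaded.config == run.config


def test_train_config_defaults_follow_published_recipe():
    cfg = TrainConfig()
    assert (cfg.epochs, cfg.batch_size, cfg.lr, cfg.input_size) == (100, 8, 5e-5, 512)
    assert cfg.optimizer == "adam"
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")
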