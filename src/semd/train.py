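"""Training loop, two-stage fine-tuning, evaluation harness, and prediction.

Training follows the published recipe: Adam at learning rate 5e-5, batch
size 8, 100 epochs at 512×512 input (the defaults of ``TrainConfig``), and
the combined cross-entropy + Dice objective.  Fine-tuning is two-stage:
with external backbone weights loaded, the backbone can be frozen for the
first ``freeze_backbone_epochs`` epochs while the segmentation head trains,
after which everything is optimized jointly.  By default the network starts
from He-normal random weights — there is a hook to load backbone weights,
but none ship with the package.

The evaluation harness reports MIoU/MPA, the mean PSNR between the
ground-truth-masked and prediction-masked RGB images (background zeroed,
8-bit peak), and per-image inference time, optionally sweeping the input
sizes 512/415/321 used in the robustness experiment.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import nn
from .data import (AnnotatedSample, AugmentationSpec, SegDataset,
                   batch_from_samples, overlay, read_image, resize_sample,
                   write_image, write_voc_mask)
from .data import augment as augment_sample
from .deeplab import ASPPConfig, SEMD, SEMDConfig
from .losses import segmentation_loss
from .metrics import ConfusionMatrix, metric_report, miou, mpa, psnr


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters; the defaults are the published recipe."""

    epochs: int = 100
    batch_size: int = 8
    lr: float = 5e-5
    optimizer: str = "adam"
    input_size: int = 512
    seed: int = 0
    freeze_backbone_epochs: int = 0
    num_classes: int = 2
    output_stride: int = 16
    se_enabled: bool = True
    augment: bool = True   # offline doubling: originals + transformed copies
    steps_per_epoch: Optional[int] = None   # optional per-epoch step cap
    val_steps: Optional[int] = None

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.freeze_backbone_epochs < 0:
            raise ValueError("freeze_backbone_epochs must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**{k: v for k, v in d.items()
                      if k in {f.name for f in dataclasses.fields(cls)}})


@dataclass
class RunLog:
    """Per-epoch history plus the config snapshot that produced it."""

    config: dict
    epochs: list[dict] = field(default_factory=list)
    best_val_miou: float = 0.0
    best_epoch: int = -1
    wall_seconds: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunLog":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def train_losses(self) -> list[float]:
        return [e["train_loss"] for e in self.epochs]


# ---- checkpoints -------------------------------------------------------------

def save_checkpoint(model: SEMD, path: Union[str, Path],
                    extra: Optional[dict] = None) -> None:
    """Serialize model weights + config to an .npz container."""
    state = model.state_dict()
    meta = {"model_config": dataclasses.asdict(model.cfg), "extra": extra or {}}
    meta["model_config"]["aspp"] = dataclasses.asdict(model.cfg.aspp)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: Union[str, Path]) -> tuple[SEMD, dict]:
    """Rebuild a model from an .npz checkpoint; returns (model, extra-meta)."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg_d = dict(meta["model_config"])
    aspp_d = cfg_d.pop("aspp")
    cfg = SEMDConfig(aspp=ASPPConfig(tuple(aspp_d["atrous_rates"]),
                                     aspp_d["branch_channels"],
                                     aspp_d["global_pool_branch"]), **cfg_d)
    model = SEMD(cfg, rng=np.random.default_rng(0))
    model.load_state_dict(state)
    model.eval()
    return model, meta.get("extra", {})


def load_backbone_weights(model: SEMD, path: Union[str, Path]) -> None:
    """Hook for externally pretrained backbone weights (npz of backbone keys)."""
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    model.backbone.load_state_dict(state)


# ---- training ----------------------------------------------------------------

def _resolve_samples(dataset, split: str, size: int) -> list[AnnotatedSample]:
    if isinstance(dataset, (str, Path)):
        dataset = SegDataset(dataset, split)
    samples = dataset.samples() if hasattr(dataset, "samples") else list(dataset)
    return [resize_sample(s, size) if s.mask.shape != (size, size) else s
            for s in samples]


def _epoch_confusion(model: SEMD, images: np.ndarray, masks: np.ndarray,
                     batch_size: int, num_classes: int) -> ConfusionMatrix:
    cm = ConfusionMatrix(num_classes)
    for lo in range(0, len(images), batch_size):
        pred = model.predict(images[lo:lo + batch_size])
        cm.update(masks[lo:lo + batch_size], pred)
    return cm


def train(dataset: Union[str, Path, SegDataset], cfg: TrainConfig,
          model: Optional[SEMD] = None,
          checkpoint_path: Optional[Union[str, Path]] = None,
          log_fn: Optional[Callable[[str], None]] = None) -> tuple[SEMD, RunLog]:
    """Train SEMD on a dataset directory; returns the best-val-MIoU model.

    Fully seeded: the same config and dataset give identical loss curves.
    Raises on an empty dataset and aborts with a diagnostic if the loss
    becomes non-finite.
    """
    t0 = time.perf_counter()
    log = log_fn or (lambda msg: None)
    train_samples = _resolve_samples(dataset, "train", cfg.input_size)
    try:
        val_samples = _resolve_samples(dataset, "val", cfg.input_size)
    except (FileNotFoundError, ValueError):
        val_samples = []
    if not train_samples:
        raise ValueError("training dataset is empty")
    if cfg.augment:
        # offline doubling: keep every original plus one transformed copy
        train_samples = train_samples + [
            augment_sample(s, AugmentationSpec(seed=cfg.seed * 10007 + i))
            for i, s in enumerate(train_samples)]

    x_train, y_train = batch_from_samples(train_samples)
    x_val, y_val = (batch_from_samples(val_samples) if val_samples else (None, None))

    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = SEMD(SEMDConfig(num_classes=cfg.num_classes,
                                output_stride=cfg.output_stride,
                                se_enabled=cfg.se_enabled,
                                input_size=cfg.input_size), rng=rng)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)

    head_params = model.aspp.parameters() + model.decoder.parameters()
    all_params = model.parameters()
    optimizer = nn.Adam(head_params if cfg.freeze_backbone_epochs > 0 else all_params,
                        lr=cfg.lr)

    run = RunLog(config=cfg.to_dict())
    best_state: Optional[dict] = None
    n = len(train_samples)
    for epoch in range(cfg.epochs):
        if epoch == cfg.freeze_backbone_epochs and cfg.freeze_backbone_epochs > 0:
            optimizer = nn.Adam(all_params, lr=cfg.lr)  # stage 2: unfreeze all
        model.train()
        order = shuffle_rng.permutation(n)
        losses = []
        steps = 0
        for lo in range(0, n, cfg.batch_size):
            if cfg.steps_per_epoch is not None and steps >= cfg.steps_per_epoch:
                break
            idx = order[lo:lo + cfg.batch_size]
            logits = model(x_train[idx])
            loss, terms = segmentation_loss(logits, y_train[idx])
            if not np.isfinite(terms.combined):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {steps}: {terms}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(terms.combined)
            steps += 1
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}

        if x_val is not None:
            model.eval()
            vloss, vsteps = [], 0
            cm = ConfusionMatrix(cfg.num_classes)
            with nn.no_grad():
                for lo in range(0, len(x_val), cfg.batch_size):
                    if cfg.val_steps is not None and vsteps >= cfg.val_steps:
                        break
                    xb, yb = x_val[lo:lo + cfg.batch_size], y_val[lo:lo + cfg.batch_size]
                    logits = model(xb)
                    _, terms = segmentation_loss(logits, yb)
                    vloss.append(terms.combined)
                    cm.update(yb, np.argmax(logits.data, axis=1))
                    vsteps += 1
            entry["val_loss"] = float(np.mean(vloss))
            entry["val_miou"] = miou(cm)
            entry["val_mpa"] = mpa(cm)
            if entry["val_miou"] >= run.best_val_miou:
                run.best_val_miou = entry["val_miou"]
                run.best_epoch = epoch
                best_state = model.state_dict()
        run.epochs.append(entry)
        log(f"epoch {epoch:3d}  train_loss={entry['train_loss']:.4f}"
            + (f"  val_loss={entry['val_loss']:.4f}  val_miou={entry['val_miou']:.4f}"
               if "val_miou" in entry else ""))

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    run.wall_seconds = time.perf_counter() - t0
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path,
                        extra={"best_val_miou": run.best_val_miou,
                               "best_epoch": run.best_epoch})
    return model, run


# ---- evaluation --------------------------------------------------------------

def masked_psnr(image: np.ndarray, gt_mask: np.ndarray,
                pred_mask: np.ndarray, n_bits: int = 8) -> float:
    """PSNR between the RGB image masked by ground truth vs. by prediction
    (background zeroed) — the segmentation-distortion convention used here."""
    img = np.asarray(image, dtype=np.float64)
    ref = img * (np.asarray(gt_mask) > 0)[..., None]
    test = img * (np.asarray(pred_mask) > 0)[..., None]
    return psnr(ref, test, n_bits)


def evaluate(model: SEMD, dataset: Union[str, Path, SegDataset],
             sizes: Sequence[int] = (512,), split: str = "val",
             batch_size: int = 4) -> dict[int, dict]:
    """Metric report per input size: MIoU, MPA, mean masked PSNR, seconds/image."""
    if isinstance(dataset, (str, Path)):
        dataset = SegDataset(dataset, split)
    base = dataset.samples() if hasattr(dataset, "samples") else list(dataset)
    if not base:
        raise ValueError("evaluation dataset is empty")
    reports: dict[int, dict] = {}
    for size in sizes:
        samples = [resize_sample(s, size) for s in base]
        images, masks = batch_from_samples(samples)
        cm = ConfusionMatrix(model.cfg.num_classes)
        psnrs = []
        t0 = time.perf_counter()
        preds = []
        for lo in range(0, len(samples), batch_size):
            preds.append(model.predict(images[lo:lo + batch_size]))
        elapsed = time.perf_counter() - t0
        pred = np.concatenate(preds, axis=0)
        cm.update(masks, pred)
        for s, p in zip(samples, pred):
            psnrs.append(masked_psnr(s.image, s.mask, p))
        report = metric_report(cm, psnrs)
        report["seconds_per_image"] = elapsed / len(samples)
        report["n_images"] = len(samples)
        reports[int(size)] = report
    return reports


def predict_files(model: SEMD, image_paths: Sequence[Union[str, Path]],
                  out_dir: Union[str, Path], alpha: float = 0.5,
                  log_fn: Optional[Callable[[str], None]] = None) -> list[Path]:
    """Segment images from disk; write a VOC mask and an overlay per input.

    Unreadable files produce a warning via `log_fn` and are skipped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = log_fn or (lambda msg: None)
    written = []
    for path in image_paths:
        path = Path(path)
        try:
            image = read_image(path)
        except Exception as exc:  # unreadable input: warn and continue
            log(f"warning: skipping unreadable image {path}: {exc}")
            continue
        from .data import normalize_image
        pred = model.predict(normalize_image(image)[None])[0]
        mask_path = out_dir / f"{path.stem}_mask.png"
        overlay_path = out_dir / f"{path.stem}_overlay.png"
        write_voc_mask(pred, mask_path)
        write_image(overlay(image, pred, alpha), overlay_path)
        written += [mask_path, overlay_path]
    return written
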