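"""Training, inference and evaluation for the double network.

Optimisation follows the published protocol: Adam (lr 1e-4, beta1 0.9,
beta2 0.999) on the minus-Dice objective at batch size 1, with an
optional auxiliary minus-Dice term on NET1's salient output weighted by
`aux_loss_weight`. Samples are reshuffled every epoch from the run
seed, so a fixed seed reproduces the loss trajectory exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .config import NetworkConfig, TrainConfig
from .data import (DatasetSplit, PadSpec, SegmentationSample, crop_back,
                   pad_to_multiple)
from .metrics import (MetricReport, UndefinedMetricError, binarize,
                      dice_loss, extract_contour, hard_dsc, hausdorff, jsc,
                      soft_dice)
from .model import DoubleNet, PredictionPair, assemble_double_net

__all__ = ["TrainLog", "train", "predict", "evaluate",
           "save_checkpoint", "load_checkpoint", "Adam"]

CHECKPOINT_VERSION = 1


class Adam:
    """Adam optimiser over a list of parameters."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


@dataclass
class TrainLog:
    """Per-epoch training history (one record per epoch)."""

    records: list = field(default_factory=list)

    def append(self, **kwargs):
        self.records.append(dict(kwargs))

    def __len__(self):
        return len(self.records)

    def last(self) -> dict:
        return self.records[-1]

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame(self.records).to_csv(path, index=False)


def _prepare(sample: SegmentationSample) -> tuple[np.ndarray, np.ndarray,
                                                  PadSpec]:
    """Pad image and mask to 32-divisible dims, shaped (1, H, W, 1)."""
    img, spec = pad_to_multiple(np.asarray(sample.image, dtype=float))
    msk, _ = pad_to_multiple(np.asarray(sample.mask, dtype=float))
    return img[None, :, :, None], msk[None, :, :, None], spec


def train(model: DoubleNet, split: DatasetSplit | list,
          cfg: TrainConfig) -> tuple[DoubleNet, TrainLog]:
    """Fit `model` on the training samples; returns (model, log).

    `split` may be a DatasetSplit (its test part is logged as
    validation each epoch) or a bare list of training samples, in which
    case the validation columns are NaN.
    """
    if isinstance(split, DatasetSplit):
        train_samples, val_samples = split.train, split.test
    else:
        train_samples, val_samples = list(split), []
    if not train_samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.adam_eps)
    lam = cfg.aux_loss_weight
    prepared = [_prepare(s)[:2] for s in train_samples]
    log = TrainLog()
    for epoch in range(1, cfg.epochs + 1):
        model.train()
        order = rng.permutation(len(prepared))
        losses, dices = [], []
        for idx in order:
            x, t = prepared[idx]
            opt.zero_grad()
            out1, out2 = model(Tensor(x), dropout_rng=rng)
            target = Tensor(t)
            loss = dice_loss(out2, target)
            if lam > 0:
                loss = loss + lam * dice_loss(out1, target)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss {loss.data} at epoch {epoch}, "
                    f"sample {train_samples[idx].id!r}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            dices.append(float(soft_dice(out2.data, t)))
        val_loss = val_dice = float("nan")
        if val_samples:
            vl, vd = [], []
            model.eval()
            for s in val_samples:
                x, t, _ = _prepare(s)
                out1, out2 = model(Tensor(x))
                vl.append(float(dice_loss(out2.data, t)
                                + lam * dice_loss(out1.data, t)))
                vd.append(float(soft_dice(out2.data, t)))
            val_loss, val_dice = float(np.mean(vl)), float(np.mean(vd))
        log.append(epoch=epoch, train_loss=float(np.mean(losses)),
                   train_dice=float(np.mean(dices)),
                   val_loss=val_loss, val_dice=val_dice)
    model.eval()
    return model, log


def predict(model: DoubleNet, image: np.ndarray, threshold: float = 0.5
            ) -> tuple[PredictionPair, np.ndarray]:
    """Padded inference on one standardized image.

    Pads to 32-divisible dims, runs the double network in inference
    mode, crops both outputs back to the raw size and thresholds the
    final map. Returns (PredictionPair, binary mask).
    """
    image = np.asarray(image, dtype=float)
    padded, spec = pad_to_multiple(image)
    pair = model.predict_arrays(padded[None, :, :, None])
    out1 = crop_back(pair.out1[0, :, :, 0], spec)
    out2 = crop_back(pair.out2[0, :, :, 0], spec)
    pair = PredictionPair(out1=out1, out2=out2)
    return pair, binarize(out2, threshold)


def evaluate(model: DoubleNet, samples: list, threshold: float = 0.5
             ) -> MetricReport:
    """Per-sample DSC / JSC / Hausdorff on binarized predictions.

    The Hausdorff distance is reported in mm when the sample carries a
    pixel spacing, else in pixels; it is left undefined (None) when
    either contour is empty.
    """
    report = MetricReport()
    for s in samples:
        _, pred_mask = predict(model, s.image, threshold=threshold)
        d = hard_dsc(pred_mask, s.mask)
        j = jsc(pred_mask, s.mask)
        try:
            hd = hausdorff(extract_contour(pred_mask),
                           extract_contour(s.mask),
                           spacing=s.pixel_spacing)
        except UndefinedMetricError:
            hd = None
        report.add(s.id, d, j, hd)
    return report


def save_checkpoint(model: DoubleNet, train_cfg: TrainConfig, path,
                    epoch: int = 0):
    """Write weights plus configs to a single .npz with a JSON header."""
    header = json.dumps({
        "version": CHECKPOINT_VERSION,
        "network": model.cfg.to_dict(),
        "train": train_cfg.to_dict(),
        "epoch": int(epoch),
        "seed": int(train_cfg.seed),
    })
    state = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez(Path(path), header=np.array(header), **state)


def load_checkpoint(path, expect_config: NetworkConfig | None = None
                    ) -> tuple[DoubleNet, dict]:
    """Rebuild the model from a checkpoint; returns (model, metadata).

    Raises ValueError if the file version is unknown or the stored
    architecture differs from `expect_config`.
    """
    with np.load(Path(path)) as npz:
        header = json.loads(str(npz["header"]))
        if header.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {header.get('version')}")
        cfg = NetworkConfig.from_dict(header["network"])
        if expect_config is not None and cfg != expect_config:
            raise ValueError("checkpoint NetworkConfig does not match the "
                             "expected architecture")
        model = assemble_double_net(cfg)
        state = {k[len("state/"):]: npz[k] for k in npz.files
                 if k.startswith("state/")}
    model.load_state_dict(state)
    model.eval()
    return model, header
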