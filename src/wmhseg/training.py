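"""Patch-based training and whole-slice inference.

Training follows a fixed recipe: Adam, categorical cross-entropy over the
three labels (non-brain / brain tissue / WMH), default learning rate 1e-5 and
batch size 16.  The epoch budget is configurable with early stopping on the
validation loss, and the validation split is by scan to avoid leakage between
patches of the same volume.  Inference tiles each slice into patch-sized
windows (non-overlapping when the slice divides evenly, overlap-averaged
otherwise) so a patch-trained model can segment whole slices.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ContractViolation, ParameterError
from .io import Volume
from .models import _ModelBase
from .nn import Adam, SoftmaxCrossEntropy, softmax
from .preprocess import TrainingPatch, patches_to_arrays

__all__ = ["TrainConfig", "LossHistory", "train", "predict_volume"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 16
    epochs: int = 50
    validation_fraction: float = 0.0
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if not 0 <= self.validation_fraction <= 0.5:
            raise ParameterError("validation_fraction must lie in [0, 0.5]")


@dataclass
class LossHistory:
    train: list[float] = field(default_factory=list)
    validation: list[float] = field(default_factory=list)
    steps: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train) + 1),
                "train_loss": self.train,
                "val_loss": self.validation if self.validation else np.nan,
            }
        )


def _scan_split(patches: Sequence[TrainingPatch], fraction: float, rng):
    """Hold out whole scans for validation (no patch-level leakage)."""
    scans = sorted({p.scan_id for p in patches})
    if fraction <= 0 or len(scans) < 2:
        if fraction > 0:
            log.warning("validation requested but only one scan; no hold-out")
        return list(patches), []
    n_val = max(1, int(round(fraction * len(scans))))
    val_scans = set(rng.permutation(scans)[:n_val])
    tr = [p for p in patches if p.scan_id not in val_scans]
    va = [p for p in patches if p.scan_id in val_scans]
    return tr, va


def train(
    model: _ModelBase,
    patches: Sequence[TrainingPatch],
    config: TrainConfig = TrainConfig(),
) -> tuple[_ModelBase, LossHistory]:
    """Optimise ``model`` in place; returns it plus per-epoch loss history.

    Deterministic for a given config seed: the scan split and every epoch's
    batch order derive from one generator.
    """
    if not patches:
        raise ParameterError("no training patches given")
    rng = np.random.default_rng(config.seed)
    train_p, val_p = _scan_split(patches, config.validation_fraction, rng)
    X, Y = patches_to_arrays(train_p)
    Xv, Yv = patches_to_arrays(val_p) if val_p else (None, None)
    _check_channels(model, X)

    opt = Adam(model.parameters(), lr=config.learning_rate)
    lossfn = SoftmaxCrossEntropy()
    hist = LossHistory()
    best_val, patience = np.inf, 0
    n = len(X)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(X[idx], training=True)
            loss = lossfn.forward(logits, Y[idx])
            opt.zero_grad()
            model.backward(lossfn.backward())
            opt.step()
            hist.steps += 1
            epoch_losses.append(loss)
        hist.train.append(float(np.mean(epoch_losses)))
        if Xv is not None:
            vlogits = model.forward(Xv, training=False)
            vloss = lossfn.forward(vlogits, Yv)
            hist.validation.append(float(vloss))
            if vloss < best_val - 1e-9:
                best_val, patience = vloss, 0
            else:
                patience += 1
                if patience >= config.early_stopping_patience:
                    log.info("early stop at epoch %d (val loss plateau)", epoch + 1)
                    break
    return model, hist


def _check_channels(model: _ModelBase, X: np.ndarray) -> None:
    c = model.spec.in_channels
    want = c if model.family == "unet" else 2 * c
    if X.shape[1] != want:
        raise ContractViolation(
            f"model expects {want} input channels, patches have {X.shape[1]}"
        )


def _tile_origins(extent: int, tile: int) -> list[int]:
    """Tile origins covering [0, extent); non-overlapping when divisible."""
    if tile > extent:
        raise ParameterError(f"tile {tile} exceeds slice extent {extent}")
    origins = list(range(0, extent - tile + 1, tile))
    if origins[-1] + tile < extent:
        origins.append(extent - tile)
    return origins


def predict_volume(
    model: _ModelBase,
    channels: Sequence[Volume],
    tile: int = 64,
    batch_size: int = 16,
) -> tuple[Volume, np.ndarray]:
    """Segment a whole volume slice by slice with tiled inference.

    Returns the per-voxel argmax label volume and the (labels, rows, cols,
    slices) probability array (probabilities sum to 1 per voxel; overlapping
    tiles are averaged and re-normalised).
    """
    if not channels:
        raise ParameterError("at least one channel volume required")
    data = np.stack([np.asarray(v.data, dtype=float) for v in channels])  # C,R,Co,S
    c, rows, cols, nsl = data.shape
    _check_channels(model, data[None, :, :, :, 0])
    n_lab = model.spec.output_labels
    probs = np.zeros((n_lab, rows, cols, nsl))
    weight = np.zeros((rows, cols, nsl))

    r_orig = _tile_origins(rows, tile)
    c_orig = _tile_origins(cols, tile)
    if len(r_orig) * tile != rows or len(c_orig) * tile != cols:
        log.info("slice not divisible by %d: using overlap-averaged tiling", tile)

    jobs = [(z, r, cc) for z in range(nsl) for r in r_orig for cc in c_orig]
    for start in range(0, len(jobs), batch_size):
        batch = jobs[start : start + batch_size]
        x = np.stack([data[:, r : r + tile, cc : cc + tile, z] for z, r, cc in batch])
        p = model.predict_proba(x)
        for bi, (z, r, cc) in enumerate(batch):
            probs[:, r : r + tile, cc : cc + tile, z] += p[bi]
            weight[r : r + tile, cc : cc + tile, z] += 1.0
    probs /= weight[None]
    labels = probs.argmax(axis=0).astype(np.int16)
    return Volume(labels, channels[0].affine.copy()), probs
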