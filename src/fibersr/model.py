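"""Multi-frame and single-image restoration autoencoders.

The multi-frame autoencoder (MFAE) receives the 11 rotation-stack frames as
input channels and emits one restored grayscale image; the single-image
autoencoder (SIAE) is the identical architecture with a 1-channel input.
The encoder is a cascade of 3x3 Conv+ReLU stages separated by 2x2 max
pooling; the decoder mirrors it with nearest-neighbour up-sampling, and a
sigmoid head keeps the output in [0, 1].

Training minimizes the composite loss

    L = w_mae * MAE + w_mse * MSE + w_ssim * (1 - SSIM)

with Adam (default learning rate 1e-4) and early stopping: if the validation
loss fails to improve by ``min_delta`` for ``patience_epochs`` (default 5)
consecutive epochs, training stops and the best-validation parameters are
restored.  The SSIM term uses the single-window formula, for which the
analytic gradient is implemented directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import nn
from .bundle import RotationStack, StackDataset
from .metrics import SSIM_K1, SSIM_K2, ssim

__all__ = [
    "ModelSpec",
    "TrainingConfig",
    "TrainingHistory",
    "Autoencoder",
    "composite_loss",
    "build_model",
    "train",
    "restore",
    "channel_ablation",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of a restoration autoencoder.

    ``input_channels`` is the number of stacked frames (11 for the MFAE,
    1 for the SIAE).  ``encoder_widths`` lists the feature widths of the
    encoder stages; a 2x2 max-pool sits between consecutive stages, so the
    input spatial size must be divisible by ``2 ** (len(widths) - 1)``.
    """

    input_channels: int = 11
    encoder_widths: tuple[int, ...] = (32, 64, 128)
    kernel_size: int = 3
    pool_size: int = 2
    output_channels: int = 1

    def __post_init__(self) -> None:
        if self.input_channels < 1 or self.output_channels != 1:
            raise ValueError("need >=1 input channel and exactly 1 output channel")
        if len(self.encoder_widths) < 1 or any(w < 1 for w in self.encoder_widths):
            raise ValueError("encoder widths must be positive")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd ('same' padding)")
        if self.pool_size != 2:
            raise ValueError("only 2x2 pooling is supported")

    @property
    def n_pool_stages(self) -> int:
        return len(self.encoder_widths) - 1

    @property
    def pool_factor(self) -> int:
        return self.pool_size**self.n_pool_stages


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings: composite-loss weights, Adam learning rate,
    and the patience-based stopping rule."""

    mae_weight: float = 0.001
    mse_weight: float = 1.0
    ssim_weight: float = 0.001
    learning_rate: float = 1e-4
    patience_epochs: int = 5
    min_delta: float = 1e-5
    max_epochs: int = 100
    batch_size: int = 4
    seed: int = 0
    literal_ssim_sign: bool = False  # strict printed-formula variant (+w*SSIM)

    def __post_init__(self) -> None:
        if min(self.mae_weight, self.mse_weight, self.ssim_weight) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.patience_epochs < 1:
            raise ValueError("patience must be at least 1 epoch")
        if self.learning_rate <= 0 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid optimization settings")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    epochs_run: int = 0
    stopped_early: bool = False
    best_epoch: int = 0  # 1-based; 0 means the untrained baseline

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.epochs_run + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
            }
        )


class Autoencoder:
    """Seeded encoder-decoder restoration network."""

    def __init__(self, spec: ModelSpec, seed: int | None = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = spec.encoder_widths
        layers: list[nn.Layer] = [nn.Conv2D(spec.input_channels, widths[0], rng, spec.kernel_size), nn.ReLU()]
        for c_in, c_out in zip(widths, widths[1:]):
            layers += [nn.MaxPool2(), nn.Conv2D(c_in, c_out, rng, spec.kernel_size), nn.ReLU()]
        for c_in, c_out in zip(widths[::-1], widths[::-1][1:]):
            layers += [nn.Upsample2(), nn.Conv2D(c_in, c_out, rng, spec.kernel_size), nn.ReLU()]
        layers += [nn.Conv2D(widths[0], spec.output_channels, rng, spec.kernel_size), nn.Sigmoid()]
        self.net = nn.Sequential(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4:
            raise ValueError("expected a (batch, channels, H, W) tensor")
        n, c, h, w = x.shape
        if c != self.spec.input_channels:
            raise ValueError(
                f"model expects {self.spec.input_channels} channels, got {c}"
            )
        if h % self.spec.pool_factor or w % self.spec.pool_factor:
            raise ValueError(
                f"spatial size must be divisible by {self.spec.pool_factor}"
            )
        return self.net.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad.astype(np.float32))

    def parameters(self) -> list[dict]:
        return self.net.parameters()

    def get_state(self) -> list[np.ndarray]:
        return self.net.get_state()

    def set_state(self, state: list[np.ndarray]) -> None:
        self.net.set_state(state)


def build_model(spec: ModelSpec, seed: int | None = 0) -> Autoencoder:
    """Instantiate a restoration autoencoder with seeded initialization."""
    return Autoencoder(spec, seed=seed)


def _loss_terms_and_grad(
    pred: np.ndarray, target: np.ndarray, config: TrainingConfig
) -> tuple[float, np.ndarray]:
    """Composite loss and its gradient w.r.t. ``pred``.

    ``pred``/``target`` are (N, 1, H, W); per-image losses are averaged over
    the batch.  The SSIM term uses the single-window formula; its gradient is
    the analytic derivative of that closed form.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    n_batch = pred.shape[0]
    n_pix = pred[0].size
    diff = pred - target

    l_mae = float(np.mean(np.abs(diff)))
    g_mae = np.sign(diff) / (n_pix * n_batch)
    l_mse = float(np.mean(diff**2))
    g_mse = 2.0 * diff / (n_pix * n_batch)

    c1 = SSIM_K1**2
    c2 = SSIM_K2**2
    axes = (1, 2, 3)
    mu_x = pred.mean(axis=axes, keepdims=True)
    mu_y = target.mean(axis=axes, keepdims=True)
    xc = pred - mu_x
    yc = target - mu_y
    var_x = (xc**2).mean(axis=axes, keepdims=True)
    var_y = (yc**2).mean(axis=axes, keepdims=True)
    cov = (xc * yc).mean(axis=axes, keepdims=True)
    n1 = 2 * mu_x * mu_y + c1
    n2 = 2 * cov + c2
    d1 = mu_x**2 + mu_y**2 + c1
    d2 = var_x + var_y + c2
    s = n1 * n2 / (d1 * d2)
    l_ssim = float(s.mean())
    # d s / d pred_i, from the quotient rule with
    # d mu_x = 1/n, d var_x = 2 xc/n, d cov = yc/n per pixel
    ds = (
        (2 * mu_y / n_pix) * n2 * d1 * d2
        + n1 * (2 * yc / n_pix) * d1 * d2
        - n1 * n2 * ((2 * mu_x / n_pix) * d2 + d1 * (2 * xc / n_pix))
    ) / (d1**2 * d2**2)
    ds /= n_batch

    if config.literal_ssim_sign:
        l_total = (
            config.mae_weight * l_mae
            + config.mse_weight * l_mse
            + config.ssim_weight * l_ssim
        )
        g_ssim = config.ssim_weight * ds
    else:
        l_total = (
            config.mae_weight * l_mae
            + config.mse_weight * l_mse
            + config.ssim_weight * (1.0 - l_ssim)
        )
        g_ssim = -config.ssim_weight * ds

    grad = config.mae_weight * g_mae + config.mse_weight * g_mse + g_ssim
    return l_total, grad


def composite_loss(
    prediction: np.ndarray,
    target: np.ndarray,
    config: TrainingConfig | None = None,
) -> float:
    """Weighted MAE + MSE + (1 - SSIM) restoration loss for one image pair."""
    config = config or TrainingConfig()
    prediction = np.asarray(prediction, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prediction.shape != target.shape:
        raise ValueError("prediction and target must share a shape")
    p = prediction.reshape(1, 1, *prediction.shape[-2:]) if prediction.ndim == 2 else prediction
    t = target.reshape(1, 1, *target.shape[-2:]) if target.ndim == 2 else target
    loss, _ = _loss_terms_and_grad(p, t, config)
    return loss


def _as_xy(split: StackDataset | tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(split, StackDataset):
        return split.stacks.astype(np.float32), split.ground_truths[:, None].astype(np.float32)
    x, y = split
    return np.asarray(x, dtype=np.float32), np.asarray(y, dtype=np.float32)


def _dataset_loss(model: Autoencoder, x: np.ndarray, y: np.ndarray, config: TrainingConfig, batch: int) -> float:
    total, n = 0.0, x.shape[0]
    for i in range(0, n, batch):
        xb, yb = x[i : i + batch], y[i : i + batch]
        loss, _ = _loss_terms_and_grad(model.forward(xb), yb, config)
        total += loss * xb.shape[0]
    return total / n


def train(
    model: Autoencoder,
    dataset: Mapping[str, StackDataset | tuple[np.ndarray, np.ndarray]],
    config: TrainingConfig,
) -> tuple[Autoencoder, TrainingHistory]:
    """Train with Adam and patience-based early stopping.

    ``dataset`` maps ``"train"`` and ``"val"`` to either
    :class:`~fibersr.bundle.StackDataset` splits or ``(inputs, targets)``
    array pairs with shapes ``(N, C, H, W)`` / ``(N, 1, H, W)``.  The
    validation loss is evaluated once before training as the stopping
    baseline, then after every epoch; parameters from the best validation
    epoch are restored on exit.
    """
    x_tr, y_tr = _as_xy(dataset["train"])
    x_va, y_va = _as_xy(dataset["val"])
    if x_tr.shape[0] == 0 or x_va.shape[0] == 0:
        raise ValueError("training and validation splits must be non-empty")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    hist = TrainingHistory()

    best_val = _dataset_loss(model, x_va, y_va, config, config.batch_size)
    best_state = model.get_state()
    stall = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(x_tr.shape[0])
        epoch_loss, seen = 0.0, 0
        for i in range(0, order.size, config.batch_size):
            idx = order[i : i + config.batch_size]
            pred = model.forward(x_tr[idx])
            loss, grad = _loss_terms_and_grad(pred, y_tr[idx], config)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            model.backward(grad)
            opt.step()
            epoch_loss += loss * idx.size
            seen += idx.size
        hist.train_loss.append(epoch_loss / seen)

        val = _dataset_loss(model, x_va, y_va, config, config.batch_size)
        hist.val_loss.append(val)
        hist.epochs_run = epoch

        if best_val - val > config.min_delta:
            best_val = val
            best_state = model.get_state()
            hist.best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience_epochs:
                hist.stopped_early = True
                break

    model.set_state(best_state)
    return model, hist


def restore(model: Autoencoder, stack: RotationStack | np.ndarray) -> np.ndarray:
    """Apply a trained model to one rotation stack (MFAE) or frame (SIAE).

    Accepts a :class:`RotationStack`, a ``(C, H, W)`` frame stack, or a
    ``(H, W)`` single frame for 1-channel models; returns the restored
    ``(H, W)`` raster in [0, 1].
    """
    if isinstance(stack, RotationStack):
        x = stack.frames
    else:
        x = np.asarray(stack, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
    if x.ndim != 3:
        raise ValueError("expected a (C, H, W) stack or (H, W) frame")
    if x.shape[0] != model.spec.input_channels:
        raise ValueError(
            f"stack has {x.shape[0]} channels but model expects "
            f"{model.spec.input_channels}"
        )
    out = model.forward(x[None])
    return np.clip(out[0, 0], 0.0, 1.0)


def _symmetric_channel_indices(angles: Sequence[float], count: int) -> np.ndarray:
    angles = np.asarray(angles, dtype=float)
    if count > angles.size:
        raise ValueError("channel count exceeds available angles")
    if count % 2 == 0:
        raise ValueError("channel counts must be odd (symmetric about 0 deg)")
    center = int(np.argmin(np.abs(angles)))
    half = count // 2
    idx = np.arange(center - half, center + half + 1)
    if idx[0] < 0 or idx[-1] >= angles.size:
        raise ValueError("angle set too small for a symmetric selection")
    return idx


def channel_ablation(
    dataset: Mapping[str, StackDataset],
    channel_counts: Sequence[int],
    config: TrainingConfig,
    encoder_widths: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Retrain the autoencoder per channel count and tabulate test SSIM.

    For each (odd) count a sub-stack symmetric about the 0-degree frame is
    cut from every split, a fresh model is trained under the identical
    budget, and mean and standard deviation of test-set SSIM are recorded.
    """
    angles = dataset["train"].angles
    rows = []
    for count in channel_counts:
        idx = _symmetric_channel_indices(angles, int(count))
        sub = {
            name: (split.stacks[:, idx], split.ground_truths[:, None])
            for name, split in dataset.items()
        }
        spec = ModelSpec(
            input_channels=int(count),
            encoder_widths=encoder_widths or ModelSpec().encoder_widths,
        )
        model = build_model(spec, seed=config.seed)
        model, hist = train(model, sub, config)
        x_te, y_te = sub["test"]
        scores = [
            ssim(np.clip(model.forward(x_te[i : i + 1])[0, 0], 0, 1), y_te[i, 0])
            for i in range(x_te.shape[0])
        ]
        scores = np.asarray(scores)
        rows.append(
            {
                "channels": int(count),
                "mean_ssim": float(scores.mean()),
                "sd_ssim": float(scores.std()),
                "epochs_run": hist.epochs_run,
            }
        )
    return pd.DataFrame(rows)


def save_model(model: Autoencoder, path: str | Path) -> None:
    """Save weights as an .npz next to a JSON architecture sidecar."""
    path = Path(path)
    arrays = {f"param_{i}": a for i, a in enumerate(model.get_state())}
    np.savez_compressed(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"spec": asdict(model.spec), "seed": model.seed}))


def load_model(path: str | Path) -> Autoencoder:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_d = meta["spec"]
    spec_d["encoder_widths"] = tuple(spec_d["encoder_widths"])
    spec = ModelSpec(**spec_d)
    model = build_model(spec, seed=meta.get("seed"))
    with np.load(path) as data:
        state = [data[f"param_{i}"] for i in range(len(data.files))]
    model.set_state(state)
    return model
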