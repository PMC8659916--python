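"""Conditional-GAN hologram-to-phase reconstruction.

A pix2pix-style model: the U-Net generator translates a normalized hologram
patch into a normalized wrapped-phase patch, and the patch discriminator
judges (hologram, phase) channel-concatenated pairs. The generator loss is
the adversarial binary cross-entropy plus a heavily weighted L1 term
(lambda = 100) against the target phase; the discriminator is trained with
BCE against labels 1 (real pairs) and 0 (generated pairs).

Because adversarial losses do not converge, model selection is driven by two
image-quality curves recorded every epoch on denormalized generator outputs:
the mean thresholding-and-summation metric (TSM) and the mean background
standard deviation over a fixed subset of images. The selected checkpoint is
the one minimizing background STD after the validation TSM has plateaued.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import (
    STD_SAMPLE_SIZE,
    auto_background_region,
    background_std,
    normalize_wrapped_phase,
    tsm,
)
from .nn import Adam, PatchDiscriminator, UNetGenerator, receptive_field

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "LossWeights",
    "TrainConfig",
    "EpochMetrics",
    "TrainingData",
    "build_generator",
    "build_discriminator",
    "bce_loss",
    "discriminator_loss",
    "generator_loss",
    "train",
    "train_generator_supervised",
    "select_best_epoch",
    "infer",
]

EPS = 1e-7  # clamp inside logs


@dataclass(frozen=True)
class GeneratorConfig:
    input_size: int = 256
    encoder_depth: int = 8
    base_filters: int = 64
    max_filters: int = 512
    dropout_decoder_layers: int = 4
    output_channels: int = 3
    input_channels: int = 3
    final_activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.input_size % (2**self.encoder_depth) != 0:
            raise ValueError("input_size must be divisible by 2^encoder_depth")
        if self.final_activation != "tanh":
            raise ValueError("only a tanh output head is supported")


@dataclass(frozen=True)
class DiscriminatorConfig:
    conv_layers: int = 6
    strides: tuple[int, ...] = (2, 2, 2, 2, 1, 1)
    base_filters: int = 64
    max_filters: int = 512
    input_channels: int = 6

    def __post_init__(self) -> None:
        if len(self.strides) != self.conv_layers:
            raise ValueError("strides list must have one entry per conv layer")


@dataclass(frozen=True)
class LossWeights:
    lambda_l1: float = 100.0
    adversarial_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.002
    epochs: int = 100
    batch_size: int = 1
    seed: int = 0
    std_sample_size: int = STD_SAMPLE_SIZE
    metric_sample_size: int | None = None  # cap on images per TSM average


@dataclass
class EpochMetrics:
    """Per-epoch quality record driving model selection."""

    epoch: int  # 1-based
    mean_tsm_train: float
    mean_tsm_val: float
    mean_std_train: float
    mean_std_val: float
    gen_loss: float = float("nan")
    disc_loss: float = float("nan")


@dataclass
class TrainingData:
    """Normalized [-1, 1] single-channel pairs, already split."""

    train_x: np.ndarray  # (N, H, W) holograms
    train_y: np.ndarray  # (N, H, W) phases
    val_x: np.ndarray
    val_y: np.ndarray

    def __post_init__(self) -> None:
        for a in (self.train_x, self.train_y, self.val_x, self.val_y):
            if a.ndim != 3:
                raise ValueError("training arrays must be (n, height, width)")
        if self.train_x.shape != self.train_y.shape or self.val_x.shape != self.val_y.shape:
            raise ValueError("hologram and phase arrays must align")


def build_generator(cfg: GeneratorConfig, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(
        input_size=cfg.input_size,
        depth=cfg.encoder_depth,
        base_filters=cfg.base_filters,
        max_filters=cfg.max_filters,
        in_channels=cfg.input_channels,
        out_channels=cfg.output_channels,
        dropout_layers=cfg.dropout_decoder_layers,
        seed=seed,
    )


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0) -> PatchDiscriminator:
    model = PatchDiscriminator(
        in_channels=cfg.input_channels,
        base_filters=cfg.base_filters,
        max_filters=cfg.max_filters,
        strides=cfg.strides,
        seed=seed,
    )
    return model


def bce_loss(scores: np.ndarray, label: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of a score map against a constant label.

    Returns the loss and its gradient with respect to the scores; scores are
    clamped away from 0/1 by ``EPS`` inside the logarithms.
    """
    s = np.clip(scores, EPS, 1.0 - EPS)
    loss = float(-np.mean(label * np.log(s) + (1.0 - label) * np.log(1.0 - s)))
    grad = (-(label / s) + (1.0 - label) / (1.0 - s)) / s.size
    return loss, grad


def discriminator_loss(scores_real: np.ndarray, scores_fake: np.ndarray) -> tuple[float, float]:
    """(L_real, L_fake): BCE of real scores vs 1 and fake scores vs 0."""
    l_real, _ = bce_loss(scores_real, 1.0)
    l_fake, _ = bce_loss(scores_fake, 0.0)
    return l_real, l_fake


def generator_loss(
    scores_fake: np.ndarray,
    generated: np.ndarray,
    target: np.ndarray,
    weights: LossWeights = LossWeights(),
) -> float:
    """Adversarial BCE (fake scored against label 1) + lambda x mean |G - y|."""
    if generated.shape != target.shape:
        raise ValueError("generated and target shapes must match")
    adv, _ = bce_loss(scores_fake, 1.0)
    l1 = float(np.mean(np.abs(generated - target)))
    return weights.adversarial_weight * adv + weights.lambda_l1 * l1


def _to3(batch: np.ndarray, channels: int) -> np.ndarray:
    """Replicate single-channel (B, H, W) data across the model's channels."""
    return np.repeat(batch[:, None], channels, axis=1)


def _phase_from_output(out: np.ndarray) -> np.ndarray:
    """Average the output channels and denormalize [-1, 1] -> radians."""
    return out.mean(axis=1) * np.pi


def _quality_metrics(
    gen: UNetGenerator,
    x: np.ndarray,
    n_tsm: int | None,
    n_std: int,
    batch: int = 8,
) -> tuple[float, float]:
    """Mean TSM and mean background STD of generator outputs on a dataset."""
    n = len(x) if n_tsm is None else min(n_tsm, len(x))
    tsms, stds = [], []
    for start in range(0, n, batch):
        xb = _to3(x[start : start + batch], gen.in_channels)
        phase = _phase_from_output(gen.forward(xb, training=False))
        for k, img in enumerate(phase):
            norm = np.clip(normalize_wrapped_phase(img), 0.0, 1.0)
            tsms.append(tsm(norm))
            if start + k < n_std:
                stds.append(background_std(img, auto_background_region(img)))
    return float(np.mean(tsms)), float(np.mean(stds))


def train(
    data: TrainingData,
    gcfg: GeneratorConfig,
    dcfg: DiscriminatorConfig,
    tcfg: TrainConfig,
    weights: LossWeights = LossWeights(),
    checkpoint_dir: str | Path | None = None,
) -> tuple[list[dict[str, np.ndarray]], list[EpochMetrics]]:
    """Adversarial training loop; one checkpoint + metric record per epoch.

    Per step: the discriminator sees one real and one generated pair (BCE
    labels 1/0), then the generator is updated through the discriminator with
    the adversarial + weighted-L1 objective. Fully seeded and deterministic
    for a fixed configuration. Raises on a non-finite loss.
    """
    gen = build_generator(gcfg, seed=tcfg.seed)
    disc = build_discriminator(dcfg, seed=tcfg.seed + 1)
    opt_g = Adam(gen.params(), lr=tcfg.learning_rate)
    opt_d = Adam(disc.params(), lr=tcfg.learning_rate)
    shuffle_rng = np.random.default_rng(tcfg.seed + 2)

    checkpoints: list[dict[str, np.ndarray]] = []
    history: list[EpochMetrics] = []
    n = len(data.train_x)
    for epoch in range(1, tcfg.epochs + 1):
        order = shuffle_rng.permutation(n)
        g_losses, d_losses = [], []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            x3 = _to3(data.train_x[idx], gcfg.input_channels)
            y3 = _to3(data.train_y[idx], gcfg.output_channels)

            opt_d.zero_grad()
            opt_g.zero_grad()
            fake = gen.forward(x3, training=True)

            s_real = disc.forward(np.concatenate([x3, y3], axis=1), training=True)
            l_real, ds = bce_loss(s_real, 1.0)
            disc.backward(ds)
            s_fake = disc.forward(np.concatenate([x3, fake], axis=1), training=True)
            l_fake, ds = bce_loss(s_fake, 0.0)
            disc.backward(ds)
            opt_d.step()

            opt_d.zero_grad()
            s_fake2 = disc.forward(np.concatenate([x3, fake], axis=1), training=True)
            l_adv, ds = bce_loss(s_fake2, 1.0)
            dfake = disc.backward(weights.adversarial_weight * ds)[:, gcfg.input_channels:]
            l1 = float(np.mean(np.abs(fake - y3)))
            dfake = dfake + weights.lambda_l1 * np.sign(fake - y3) / fake.size
            gen.backward(dfake)
            opt_g.step()

            g_loss = weights.adversarial_weight * l_adv + weights.lambda_l1 * l1
            d_loss = l_real + l_fake
            if not (np.isfinite(g_loss) and np.isfinite(d_loss)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (gen {g_loss}, disc {d_loss})"
                )
            g_losses.append(g_loss)
            d_losses.append(d_loss)

        tsm_tr, std_tr = _quality_metrics(
            gen, data.train_x, tcfg.metric_sample_size, tcfg.std_sample_size)
        tsm_va, std_va = _quality_metrics(
            gen, data.val_x, tcfg.metric_sample_size, tcfg.std_sample_size)
        history.append(EpochMetrics(
            epoch=epoch, mean_tsm_train=tsm_tr, mean_tsm_val=tsm_va,
            mean_std_train=std_tr, mean_std_val=std_va,
            gen_loss=float(np.mean(g_losses)), disc_loss=float(np.mean(d_losses)),
        ))
        state = gen.state_dict()
        checkpoints.append(state)
        if checkpoint_dir is not None:
            path = Path(checkpoint_dir)
            path.mkdir(parents=True, exist_ok=True)
            np.savez(path / f"generator_epoch{epoch:03d}.npz", **state)
    return checkpoints, history


def train_generator_supervised(
    data: TrainingData,
    gcfg: GeneratorConfig,
    tcfg: TrainConfig,
    loss: str = "l1",
) -> tuple[list[dict[str, np.ndarray]], list[EpochMetrics]]:
    """Plain U-Net baseline: the generator alone, no adversary.

    ``loss`` is "l1" (mean absolute error) or "log" (pixel-wise BCE on
    outputs and targets mapped to [0, 1]).
    """
    if loss not in ("l1", "log"):
        raise ValueError("loss must be 'l1' or 'log'")
    gen = build_generator(gcfg, seed=tcfg.seed)
    opt = Adam(gen.params(), lr=tcfg.learning_rate)
    shuffle_rng = np.random.default_rng(tcfg.seed + 2)
    checkpoints, history = [], []
    n = len(data.train_x)
    for epoch in range(1, tcfg.epochs + 1):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            x3 = _to3(data.train_x[idx], gcfg.input_channels)
            y3 = _to3(data.train_y[idx], gcfg.output_channels)
            opt.zero_grad()
            out = gen.forward(x3, training=True)
            if loss == "l1":
                value = float(np.mean(np.abs(out - y3)))
                grad = np.sign(out - y3) / out.size
            else:
                p = np.clip((out + 1.0) / 2.0, EPS, 1.0 - EPS)
                q = (y3 + 1.0) / 2.0
                value = float(-np.mean(q * np.log(p) + (1 - q) * np.log(1 - p)))
                grad = ((p - q) / (p * (1.0 - p))) / (2.0 * out.size)
            if not np.isfinite(value):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            gen.backward(grad)
            opt.step()
            losses.append(value)
        tsm_tr, std_tr = _quality_metrics(
            gen, data.train_x, tcfg.metric_sample_size, tcfg.std_sample_size)
        tsm_va, std_va = _quality_metrics(
            gen, data.val_x, tcfg.metric_sample_size, tcfg.std_sample_size)
        history.append(EpochMetrics(
            epoch=epoch, mean_tsm_train=tsm_tr, mean_tsm_val=tsm_va,
            mean_std_train=std_tr, mean_std_val=std_va,
            gen_loss=float(np.mean(losses)),
        ))
        checkpoints.append(gen.state_dict())
    return checkpoints, history


def select_best_epoch(
    metrics: list[EpochMetrics], tsm_plateau_tol: float = 0.02
) -> int:
    """Pick the checkpoint epoch: minimal validation STD once TSM has plateaued.

    The plateau starts at the first epoch whose validation TSM changed from
    the previous epoch by at most ``tsm_plateau_tol``; among that epoch and
    all later ones the epoch with the smallest validation background STD wins
    (ties go to the earliest). If the TSM never plateaus the global STD
    minimizer is returned with a warning.
    """
    if len(metrics) < 2:
        raise ValueError("need at least 2 epochs of metrics")
    plateau_start = None
    for prev, cur in zip(metrics, metrics[1:]):
        if abs(cur.mean_tsm_val - prev.mean_tsm_val) <= tsm_plateau_tol:
            plateau_start = cur.epoch
            break
    if plateau_start is None:
        warnings.warn("validation TSM never plateaued; falling back to global STD minimum",
                      stacklevel=2)
        candidates = metrics
    else:
        candidates = [m for m in metrics if m.epoch >= plateau_start]
    best = min(candidates, key=lambda m: (m.mean_std_val, m.epoch))
    return best.epoch


def infer(
    gen: UNetGenerator,
    hologram: np.ndarray,
    checkpoint: dict[str, np.ndarray] | None = None,
    resize: bool = False,
) -> np.ndarray:
    """Reconstruct the wrapped phase (radians) of a normalized hologram.

    ``hologram`` is a [-1, 1]-normalized 2-D array. Inputs matching the
    trained patch size are translated directly; larger frames are tiled on
    the non-overlapping floor grid and reassembled (the remainder outside the
    grid is dropped, as in dataset construction). Smaller inputs are an error
    unless ``resize`` is set, in which case they are rescaled to the patch
    size. Inference is deterministic: dropout is off.
    """
    if checkpoint is not None:
        gen.load_state_dict(checkpoint)
    hologram = np.asarray(hologram, dtype=np.float64)
    if hologram.ndim != 2:
        raise ValueError("expected a single 2-D hologram")
    ps = gen.input_size
    h, w = hologram.shape
    if (h, w) == (ps, ps):
        out = gen.forward(_to3(hologram[None], gen.in_channels), training=False)
        return _phase_from_output(out)[0]
    if h < ps or w < ps:
        if not resize:
            raise ValueError(
                f"input {h}x{w} smaller than the trained patch size {ps}; "
                "pass resize=True to rescale"
            )
        from skimage.transform import resize as _resize

        small = _resize(hologram, (ps, ps), preserve_range=True, anti_aliasing=True)
        out = gen.forward(_to3(small[None], gen.in_channels), training=False)
        return _phase_from_output(out)[0]
    ny, nx = h // ps, w // ps
    result = np.zeros((ny * ps, nx * ps))
    for i in range(ny):
        for j in range(nx):
            tile = hologram[i * ps : (i + 1) * ps, j * ps : (j + 1) * ps]
            out = gen.forward(_to3(tile[None], gen.in_channels), training=False)
            result[i * ps : (i + 1) * ps, j * ps : (j + 1) * ps] = _phase_from_output(out)[0]
    return result


def describe_architecture(gcfg: GeneratorConfig, dcfg: DiscriminatorConfig) -> dict:
    """JSON-ready descriptor, including the discriminator's receptive field."""
    kernels = [4 if s == 2 else 3 for s in dcfg.strides]
    return {
        "generator": {
            "input_size": gcfg.input_size,
            "encoder_depth": gcfg.encoder_depth,
            "base_filters": gcfg.base_filters,
            "max_filters": gcfg.max_filters,
            "dropout_decoder_layers": gcfg.dropout_decoder_layers,
            "channels": [gcfg.input_channels, gcfg.output_channels],
            "final_activation": gcfg.final_activation,
        },
        "discriminator": {
            "conv_layers": dcfg.conv_layers,
            "strides": list(dcfg.strides),
            "kernels": kernels,
            "receptive_field_px": receptive_field(kernels, list(dcfg.strides)),
            "input_channels": dcfg.input_channels,
        },
    }
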