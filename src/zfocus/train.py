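"""Training loop: seeded mini-batch sampling, cross-entropy, Adam.

Each mini-batch element is drawn independently and uniformly over every
(stack, slice) image of the training split, then passes through the
preprocessing chain *random crop → random flip/rotation → block-mean
downsampling → per-image min–max normalization*; its label is the z-bin of
the slice's annotated defocus.  The loss is the mean cross entropy between
the softmax output and the annotated bin, optimized with Adam
(lr 1e-4, β1 = 0.9, β2 = 0.999 by default).

Two presets are provided: ``paper`` is the full-scale configuration
(1000-px crops, 100,000 steps — GPU-scale), ``desk`` is a CPU-feasible
scaled-down configuration (600-px synthetic fields, 256-px crops, 4×
downsampling, 2,000 steps, batch 16) used throughout the test battery.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import zstack as zs
from .binning import BinScheme, label_of, make_bins
from .model import ModelConfig, Network, initialize
from .zstack import DatasetManifest, read_zstack

__all__ = ["TrainConfig", "PRESETS", "sample_minibatch", "train_model",
           "subset_training", "StackCache"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 25
    steps: int = 100_000
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    downsample_factor: int = 4
    crop: int = 1000
    bins: BinScheme = field(default_factory=lambda: make_bins(-20, 20, 1))
    subset_size: int | None = None
    loss_ema_window: int = 50

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")

    def model_config(self, **overrides) -> ModelConfig:
        return ModelConfig(
            input_crop=self.crop,
            downsample_factor=self.downsample_factor,
            n_bins=self.bins.n_bins,
            **overrides,
        )


PRESETS: dict[str, dict] = {
    # full-scale settings: full-resolution crops, GPU-scale step count
    "paper": dict(batch_size=25, steps=100_000, crop=1000, downsample_factor=4),
    # CPU-feasible scaled-down settings used by the synthetic experiments
    "desk": dict(batch_size=16, steps=2_000, crop=256, downsample_factor=4),
}


class StackCache:
    """In-memory cache of stack pixel data keyed by path."""

    def __init__(self, manifest: DatasetManifest):
        self._paths = manifest.paths
        self._stacks: dict[str, zs.ZStack] = {}

    def get(self, path: str) -> zs.ZStack:
        if path not in self._stacks:
            self._stacks[path] = read_zstack(path)
        return self._stacks[path]


def _image_index(manifest: DatasetManifest, cache: StackCache,
                 bins: BinScheme):
    """Flat list of (path, slice_index, label) over every training image.

    Labeling the whole split up front surfaces annotation errors (a slice
    whose z falls outside the bin coverage) immediately, naming the stack.
    """
    index = []
    for path in manifest.paths:
        stack = cache.get(path)
        for i, z in enumerate(stack.z_positions):
            try:
                index.append((path, i, label_of(bins, float(z))))
            except ValueError as exc:
                raise ValueError(f"stack {path}: {exc}") from exc
    return index


def _prepare(px, crop_size, factor, rng):
    patch = zs.crop(px, crop_size, mode="random", rng=rng)
    patch = zs.augment(patch, rng)
    patch = zs.downsample(patch, factor)
    return zs.normalize(patch)


def sample_minibatch(
    manifest: DatasetManifest,
    config: TrainConfig,
    rng: np.random.Generator,
    cache: StackCache | None = None,
):
    """One batch of (images, labels); images shape (B, side, side)."""
    cache = cache or StackCache(manifest)
    index = _image_index(manifest, cache, config.bins)
    if not index:
        raise ValueError("training split is empty")
    images, labels = [], []
    for k in rng.integers(0, len(index), size=config.batch_size):
        path, i, label = index[k]
        labels.append(label)
        images.append(
            _prepare(cache.get(path).data[i], config.crop,
                     config.downsample_factor, rng)
        )
    return np.stack(images), np.asarray(labels)


def subset_training(manifest: DatasetManifest, n: int, seed: int) -> DatasetManifest:
    """Uniform sample of ``n`` stacks without replacement (seeded)."""
    if n > len(manifest):
        raise ValueError(f"requested {n} stacks but manifest has {len(manifest)}")
    if n == len(manifest):
        return manifest
    keep = np.random.default_rng(seed).choice(len(manifest), size=n, replace=False)
    table = manifest.table.iloc[np.sort(keep)].reset_index(drop=True)
    return DatasetManifest(table, seed=manifest.seed)


def train_model(
    manifest: DatasetManifest,
    train_config: TrainConfig,
    model_config: ModelConfig | None = None,
    progress: bool = False,
) -> tuple[Network, pd.DataFrame]:
    """Train a network on the train split of ``manifest``.

    Returns the trained network and a per-step log (step, loss, loss_ema,
    wall_s).  Reproducible: the model init, batch sequence and dropout all
    derive from ``train_config.seed``.
    """
    from ._nn import AdamState

    train_split = manifest.subset("train")
    if len(train_split) == 0:
        raise ValueError("manifest has no stacks tagged 'train'; split it first")
    if train_config.subset_size is not None:
        train_split = subset_training(
            train_split, train_config.subset_size, train_config.seed
        )
    model_config = model_config or train_config.model_config()
    if model_config.input_crop != train_config.crop or (
        model_config.downsample_factor != train_config.downsample_factor
        or model_config.n_bins != train_config.bins.n_bins
    ):
        raise ValueError("model config inconsistent with training config")

    seeds = np.random.SeedSequence(train_config.seed).spawn(3)
    init_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    batch_rng = np.random.default_rng(seeds[1])
    dropout_rng = np.random.default_rng(seeds[2])

    net = initialize(model_config, init_seed, bins=train_config.bins)
    adam = AdamState(net.params, train_config.learning_rate,
                     train_config.beta1, train_config.beta2)
    cache = StackCache(train_split)
    index = _image_index(train_split, cache, train_config.bins)

    alpha = 2.0 / (train_config.loss_ema_window + 1)
    ema = None
    log_rows = []
    t0 = time.monotonic()
    for step in range(train_config.steps):
        images, labels = [], []
        for k in batch_rng.integers(0, len(index), size=train_config.batch_size):
            path, i, label = index[k]
            labels.append(label)
            images.append(
                _prepare(cache.get(path).data[i], train_config.crop,
                         train_config.downsample_factor, batch_rng)
            )
        x = np.stack(images)
        y = np.asarray(labels)
        loss, grads = net.loss_and_grads(x, y, dropout_rng)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged: non-finite loss at step {step}"
            )
        adam.update(net.params, grads)
        ema = loss if ema is None else (1 - alpha) * ema + alpha * loss
        log_rows.append(
            (step, loss, ema, time.monotonic() - t0)
        )
        if progress and (step + 1) % 100 == 0:
            print(f"step {step + 1}/{train_config.steps}  "
                  f"loss {loss:.3f}  ema {ema:.3f}", flush=True)
    log = pd.DataFrame(log_rows, columns=["step", "loss", "loss_ema", "wall_s"])
    return net, log
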