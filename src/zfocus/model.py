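"""The autofocus CNN: two convolution blocks and two fully connected layers.

Architecture (input is a single-channel square image, the crop after
downsampling):

* conv 10×10×1 → 32 features, stride 1, zero padding preserving the size,
  ReLU, then 5×5 max pooling with stride 5;
* conv 10×10×32 → 64 features, same padding, ReLU, 5×5/5 max pooling;
* fully connected layer to 1024 neurons, ReLU, dropout (p = 0.5, training
  only);
* fully connected layer to one neuron per z-bin, softmax.

Weights are initialized from a Gaussian with mean 0 and standard deviation
0.1 truncated at two standard deviations; all biases start at 0.1.

The feature-map side shrinks by a factor of 5 at each pooling layer (floor
on non-divisible sizes), so a cell ~100 px across at full camera resolution
spans ~25/5/1 px through the layers at 4× downsampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _nn
from .binning import BinScheme

__all__ = ["ModelConfig", "Network", "count_parameters", "initialize",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters shaping the network.

    The network input side is ``input_crop // downsample_factor`` and must
    divide exactly; feature counts and widths default to the reference
    architecture but are configurable (small settings are useful for fast
    experiments and for enumerating parameter counts by hand).
    """

    input_crop: int = 1000
    downsample_factor: int = 4
    n_bins: int = 41
    conv1_features: int = 32
    conv2_features: int = 64
    kernel: int = 10
    pool: int = 5
    fc1_width: int = 1024
    dropout_p: float = 0.5
    init_sd: float = 0.1
    init_trunc_sd: float = 2.0
    init_bias: float = 0.1
    normalization: str = "minmax"

    @property
    def input_side(self) -> int:
        if self.input_crop % self.downsample_factor:
            raise ValueError(
                f"crop {self.input_crop} not divisible by downsampling "
                f"factor {self.downsample_factor}"
            )
        return self.input_crop // self.downsample_factor

    def feature_sides(self) -> tuple[int, int, int]:
        """Spatial sides (input, after pool 1, after pool 2)."""
        s0 = self.input_side
        s1 = s0 // self.pool
        s2 = s1 // self.pool
        if s2 < 1:
            raise ValueError(f"input side {s0} collapses below 1 px after pooling")
        return s0, s1, s2

    def layer_shapes(self) -> dict[str, tuple]:
        _, _, s2 = self.feature_sides()
        k, c1, c2 = self.kernel, self.conv1_features, self.conv2_features
        return {
            "conv1_w": (k, k, 1, c1),
            "conv1_b": (c1,),
            "conv2_w": (k, k, c1, c2),
            "conv2_b": (c2,),
            "fc1_w": (s2 * s2 * c2, self.fc1_width),
            "fc1_b": (self.fc1_width,),
            "fc2_w": (self.fc1_width, self.n_bins),
            "fc2_b": (self.n_bins,),
        }


def count_parameters(config: ModelConfig) -> int:
    """Exact number of trainable scalars (weights + biases)."""
    return sum(int(np.prod(shape)) for shape in config.layer_shapes().values())


def _truncated_normal(rng: np.random.Generator, shape, sd: float, trunc: float):
    """Gaussian(0, sd) with redraw outside ±trunc·sd (TF-style truncation)."""
    out = rng.normal(0.0, sd, size=shape)
    bad = np.abs(out) > trunc * sd
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > trunc * sd
    return out.astype(np.float32)


class Network:
    """Parameter tensors plus the config that shaped them."""

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray],
                 bins: BinScheme | None = None):
        expected = config.layer_shapes()
        for name, shape in expected.items():
            if params[name].shape != shape:
                raise ValueError(
                    f"parameter {name} has shape {params[name].shape}, "
                    f"expected {shape}"
                )
        self.config = config
        self.params = params
        self.bins = bins

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward -----------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        side = self.config.input_side
        if x.shape[1] != side or x.shape[2] != side:
            raise ValueError(
                f"network input must be {side}x{side}, got {x.shape[1:3]}"
            )
        return x[..., None]  # add channel axis

    def forward(
        self,
        x: np.ndarray,
        train_mode: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Bin probabilities for a batch (or single image); rows sum to 1."""
        return np.exp(self.forward_log_probs(x, train_mode, rng))

    def forward_log_probs(self, x, train_mode=False, rng=None) -> np.ndarray:
        acts = self._forward_internal(self._check_input(x), train_mode, rng)
        return acts["log_p"]

    def _forward_internal(self, x, train_mode, rng):
        p = self.params
        cfg = self.config
        if train_mode and rng is None:
            raise ValueError("train-mode forward needs an rng for dropout")
        a1, cols1 = _nn.conv2d_forward(x, p["conv1_w"], p["conv1_b"])
        r1 = _nn.relu(a1)
        p1, idx1 = _nn.maxpool_forward(r1, cfg.pool)
        a2, cols2 = _nn.conv2d_forward(p1, p["conv2_w"], p["conv2_b"])
        r2 = _nn.relu(a2)
        p2, idx2 = _nn.maxpool_forward(r2, cfg.pool)
        flat = p2.reshape(p2.shape[0], -1)
        h1 = _nn.relu(flat @ p["fc1_w"] + p["fc1_b"])
        if train_mode:
            mask = (rng.random(h1.shape) >= cfg.dropout_p).astype(np.float32)
            mask /= max(1.0 - cfg.dropout_p, 1e-12)
            h1d = h1 * mask
        else:
            mask = None
            h1d = h1
        logits = h1d @ p["fc2_w"] + p["fc2_b"]
        return {
            "x": x, "a1": a1, "cols1": cols1, "r1": r1, "idx1": idx1, "p1": p1,
            "a2": a2, "cols2": cols2, "r2": r2, "idx2": idx2, "p2": p2,
            "flat": flat, "h1": h1, "mask": mask, "h1d": h1d,
            "log_p": _nn.log_softmax(logits),
        }

    # -- backward ----------------------------------------------------------

    def loss_and_grads(self, x, labels, rng):
        """Mean cross-entropy over the batch and gradients for every tensor."""
        x = self._check_input(x)
        labels = np.asarray(labels)
        acts = self._forward_internal(x, train_mode=True, rng=rng)
        loss = _nn.cross_entropy_from_log_probs(acts["log_p"], labels)
        p, cfg = self.params, self.config
        b = x.shape[0]

        d_logits = np.exp(acts["log_p"])
        d_logits[np.arange(b), labels] -= 1.0
        d_logits /= b
        grads = {}
        grads["fc2_w"] = acts["h1d"].T @ d_logits
        grads["fc2_b"] = d_logits.sum(axis=0)
        d_h1 = d_logits @ p["fc2_w"].T
        if acts["mask"] is not None:
            d_h1 = d_h1 * acts["mask"]
        d_h1 *= acts["h1"] > 0
        grads["fc1_w"] = acts["flat"].T @ d_h1
        grads["fc1_b"] = d_h1.sum(axis=0)
        d_flat = d_h1 @ p["fc1_w"].T
        d_p2 = d_flat.reshape(acts["p2"].shape)
        d_r2 = _nn.maxpool_backward(d_p2, acts["idx2"], acts["r2"].shape, cfg.pool)
        d_a2 = d_r2 * (acts["a2"] > 0)
        grads["conv2_w"], grads["conv2_b"], d_p1 = _nn.conv2d_backward(
            d_a2, acts["cols2"], p["conv2_w"], need_dx=True
        )
        d_r1 = _nn.maxpool_backward(d_p1, acts["idx1"], acts["r1"].shape, cfg.pool)
        d_a1 = d_r1 * (acts["a1"] > 0)
        grads["conv1_w"], grads["conv1_b"], _ = _nn.conv2d_backward(
            d_a1, acts["cols1"], p["conv1_w"], need_dx=False
        )
        return loss, grads


def initialize(config: ModelConfig, seed: int,
               bins: BinScheme | None = None) -> Network:
    """Fresh network with truncated-normal weights and constant biases."""
    rng = np.random.default_rng(seed)
    params = {}
    for name, shape in config.layer_shapes().items():
        if name.endswith("_b"):
            params[name] = np.full(shape, config.init_bias, dtype=np.float32)
        else:
            params[name] = _truncated_normal(
                rng, shape, config.init_sd, config.init_trunc_sd
            )
    return Network(config, params, bins=bins)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(net: Network, path) -> None:
    """Single-archive checkpoint: config + bin scheme + parameter tensors."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(net.config),
        "bins": net.bins.to_dict() if net.bins is not None else None,
    }
    arrays = dict(net.params)
    arrays["_meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> Network:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["_meta_json"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        params = {k: archive[k] for k in archive.files if k != "_meta_json"}
    config = ModelConfig(**meta["config"])
    bins = BinScheme.from_dict(meta["bins"]) if meta["bins"] else None
    return Network(config, params, bins=bins)
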