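"""Single-image z-inference and the evaluation battery.

Testing protocol: the *center* crop of each image (no augmentation) is
downsampled, normalized and passed through the network; the inferred
z-position is the center of the bin with the highest predicted probability
(exact ties broken toward the lower bin index).  The error of an estimate is
``inferred − annotated`` in µm.

``evaluate`` scores every slice of every stack in a manifest split and
returns an :class:`ErrorStats`; ``confusion_map`` builds the conditional
probability matrix P(inferred bin | actual bin).  Both accept any estimator
(the CNN, a quantizing oracle, a profile-based baseline) so reference
estimators can be pushed through the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import zstack as zs
from .binning import BinScheme, center_of, label_of
from .model import Network
from .zstack import DatasetManifest, read_zstack

__all__ = [
    "preprocess",
    "infer_z",
    "CnnEstimator",
    "QuantizingOracle",
    "TrueZOracle",
    "ErrorStats",
    "evaluate",
    "confusion_map",
    "bimodal",
]


def preprocess(image, config) -> np.ndarray:
    """Testing-time chain: center crop → downsample → min–max normalize."""
    px = zs.crop(image, config.input_crop, mode="center")
    px = zs.downsample(px, config.downsample_factor)
    return zs.normalize(px)


def infer_z(net: Network, image) -> tuple[float, np.ndarray]:
    """Estimate the defocus (µm) of one image; also returns the softmax.

    The full probability vector is needed downstream for failure-mode
    diagnostics (e.g. bimodal outputs from mixed floor/ceiling populations).
    """
    if net.bins is None:
        raise ValueError("network has no bin scheme; train or attach one")
    x = preprocess(image, net.config)
    probs = net.forward(x)[0]
    label = int(np.argmax(probs))  # argmax takes the lowest index on ties
    return center_of(net.bins, label), probs


def bimodal(probs: np.ndarray, level: float = 0.3) -> bool:
    """True when two separate local maxima each carry > ``level`` mass."""
    p = np.asarray(probs)
    left = np.r_[-np.inf, p[:-1]]
    right = np.r_[p[1:], -np.inf]
    peaks = (p > level) & (p >= left) & (p >= right)
    return int(peaks.sum()) >= 2


class CnnEstimator:
    """Adapter: network → callable(image) -> z estimate in µm."""

    wants_true_z = False

    def __init__(self, net: Network):
        self.net = net
        self.last_probs: np.ndarray | None = None

    def __call__(self, image) -> float:
        z, probs = infer_z(self.net, image)
        self.last_probs = probs
        return z

    def batch(self, images: np.ndarray) -> np.ndarray:
        """Vectorized estimates for preprocessed-size raw images."""
        x = np.stack([preprocess(im, self.net.config) for im in images])
        probs = self.net.forward(x)
        labels = probs.argmax(axis=1)
        return np.array([center_of(self.net.bins, int(l)) for l in labels])


class TrueZOracle:
    """Reference estimator returning the annotated z exactly."""

    wants_true_z = True

    def __call__(self, image, z_true: float) -> float:
        return z_true


class QuantizingOracle:
    """Reference estimator returning the bin center of the true z.

    Isolates pure quantization error: for z uniform over the span its MSE
    tends to width²/12.
    """

    wants_true_z = True

    def __init__(self, bins: BinScheme):
        self.bins = bins

    def __call__(self, image, z_true: float) -> float:
        return center_of(self.bins, label_of(self.bins, z_true))


@dataclass(frozen=True)
class ErrorStats:
    """Signed per-image errors (inferred − annotated, µm) and summaries."""

    errors: np.ndarray
    tolerances: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.errors)

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.errors))

    @property
    def error_sd(self) -> float:
        return float(np.std(self.errors))

    @property
    def mse(self) -> float:
        return float(np.mean(np.square(self.errors)))

    def fraction_within(self, tol: float) -> float:
        return float(np.mean(np.abs(self.errors) <= tol))

    def summary(self) -> pd.DataFrame:
        rows = {
            "n_images": self.n,
            "mean_error_um": self.mean_error,
            "error_sd_um": self.error_sd,
            "mse_um2": self.mse,
        }
        for tol in self.tolerances:
            rows[f"frac_within_{tol:g}um"] = self.fraction_within(tol)
        return pd.DataFrame([rows])


def _call_estimator(estimator, image, z_true):
    if getattr(estimator, "wants_true_z", False):
        return estimator(image, z_true)
    return estimator(image)


def _iter_slices(manifest: DatasetManifest):
    for path in manifest.paths:
        stack = read_zstack(path)
        for i, z in enumerate(stack.z_positions):
            yield stack.data[i], float(z)


def evaluate(
    estimator,
    manifest: DatasetManifest,
    tolerances=(1.0, 2.0),
) -> ErrorStats:
    """Score every slice of every stack in ``manifest`` with ``estimator``.

    ``estimator`` is any callable(image) -> z in µm (reference estimators may
    declare ``wants_true_z`` to receive the annotation — real estimators
    never see it).
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    errors = [
        _call_estimator(estimator, image, z) - z
        for image, z in _iter_slices(manifest)
    ]
    return ErrorStats(np.asarray(errors, dtype=float), tuple(tolerances))


def confusion_map(
    estimator,
    manifest: DatasetManifest,
    bins: BinScheme,
) -> tuple[np.ndarray, np.ndarray]:
    """P(inferred bin | actual bin) plus per-actual-bin sample counts.

    Rows with at least one sample are normalized to sum to 1; empty rows are
    all zero.
    """
    counts = np.zeros((bins.n_bins, bins.n_bins))
    for image, z in _iter_slices(manifest):
        actual = label_of(bins, z)
        inferred = label_of(bins, _call_estimator(estimator, image, z))
        counts[actual, inferred] += 1
    totals = counts.sum(axis=1)
    probs = np.divide(
        counts, totals[:, None], out=np.zeros_like(counts), where=totals[:, None] > 0
    )
    return probs, totals.astype(int)
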