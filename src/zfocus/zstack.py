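"""Annotated z-stacks: data model, TIFF I/O, manifests, and image primitives.

A z-stack is a series of grayscale bright-field images of the same field of
view, acquired at successive axial positions.  Each stack carries a per-slice
signed defocus in µm relative to a manually annotated in-focus slice.

Sign convention (fixed throughout the package): **positive z means the image
was acquired above the plane of best focus**.  Slice indices are 0-based.

On disk a stack is a multi-page TIFF (8- or 16-bit grayscale, page order =
slice order) plus a JSON sidecar ``<stack>.meta.json`` with keys
``z_step_um``, ``focal_index`` and ``pixel_pitch_nm``.  A dataset is described
by a tab-separated manifest with columns ``path``, ``focal_index``,
``z_step_um``, ``split`` and ``seed``.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Image",
    "ZStack",
    "DatasetManifest",
    "read_zstack",
    "write_zstack",
    "read_manifest",
    "write_manifest",
    "split_dataset",
    "crop",
    "downsample",
    "augment",
    "normalize",
    "DIHEDRAL_ORDER",
]

MANIFEST_COLUMNS = ["path", "focal_index", "z_step_um", "split", "seed"]


@dataclass(frozen=True)
class Image:
    """A single 2-D grayscale raster with its physical pixel pitch."""

    pixels: np.ndarray
    pixel_pitch_nm: float = 60.0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"image must be 2-D and non-empty, got shape {px.shape}")
        if np.issubdtype(px.dtype, np.floating) and not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")


@dataclass(frozen=True)
class ZStack:
    """An ordered series of slices with per-slice defocus annotations.

    ``data`` has shape ``(n_slices, height, width)``; ``z_positions`` (µm) is
    strictly increasing and is exactly 0 at ``focal_index``.
    """

    data: np.ndarray
    z_positions: np.ndarray
    focal_index: int
    pixel_pitch_nm: float = 60.0

    def __post_init__(self):
        data = np.asarray(self.data)
        z = np.asarray(self.z_positions, dtype=float)
        if data.ndim != 3 or data.shape[0] < 2:
            raise ValueError("a z-stack needs >= 2 slices of 2-D images")
        if len(z) != data.shape[0]:
            raise ValueError("z_positions length must match the slice count")
        if not np.all(np.diff(z) > 0):
            raise ValueError("z_positions must be strictly increasing")
        if not 0 <= self.focal_index < data.shape[0]:
            raise IndexError("focal_index out of range")
        if z[self.focal_index] != 0.0:
            raise ValueError("z_positions[focal_index] must be exactly 0")
        object.__setattr__(self, "z_positions", z)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def z_step_um(self) -> float:
        return float(self.z_positions[1] - self.z_positions[0])

    def slice(self, i: int) -> Image:
        return Image(self.data[i], self.pixel_pitch_nm)

    @classmethod
    def from_step(
        cls,
        data: np.ndarray,
        focal_index: int,
        z_step_um: float,
        pixel_pitch_nm: float = 60.0,
    ) -> "ZStack":
        n = np.asarray(data).shape[0]
        z = (np.arange(n) - focal_index) * float(z_step_um)
        return cls(data, z, focal_index, pixel_pitch_nm)


class StackFormatError(ValueError):
    """Raised for missing/corrupt stack metadata or invalid page structure."""


def _meta_path(path: os.PathLike) -> Path:
    return Path(str(path) + ".meta.json")


def read_zstack(path: os.PathLike) -> ZStack:
    """Read a multi-page TIFF stack and its JSON metadata sidecar."""
    path = Path(path)
    meta_path = _meta_path(path)
    if not meta_path.exists():
        raise StackFormatError(f"missing metadata sidecar {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
        z_step = float(meta["z_step_um"])
        focal_index = int(meta["focal_index"])
        pitch = float(meta.get("pixel_pitch_nm", 60.0))
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise StackFormatError(f"corrupt metadata in {meta_path}: {exc}") from exc
    data = tifffile.imread(path)
    if data.ndim == 2 or data.shape[0] < 2:
        raise StackFormatError(f"{path}: a z-stack needs >= 2 TIFF pages")
    return ZStack.from_step(data, focal_index, z_step, pitch)


def write_zstack(stack: ZStack, path: os.PathLike) -> None:
    """Write a stack as multi-page TIFF + sidecar, atomically (tmp + rename)."""
    path = Path(path)
    step = np.diff(stack.z_positions)
    if not np.allclose(step, step[0]):
        raise ValueError("only uniformly spaced stacks can be written to TIFF+sidecar")
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tif.tmp")
    os.close(fd)
    try:
        tifffile.imwrite(tmp, stack.data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    meta = {
        "z_step_um": float(step[0]),
        "focal_index": int(stack.focal_index),
        "pixel_pitch_nm": float(stack.pixel_pitch_nm),
    }
    tmp_meta = str(_meta_path(path)) + ".tmp"
    with open(tmp_meta, "w") as fh:
        json.dump(meta, fh)
    os.replace(tmp_meta, _meta_path(path))


# ---------------------------------------------------------------------------
# dataset manifests


@dataclass
class DatasetManifest:
    """Table of stacks with annotations and train/test split tags."""

    table: pd.DataFrame
    seed: int | None = None

    def __post_init__(self):
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        if self.table["path"].duplicated().any():
            raise ValueError("manifest paths must be unique")

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(
            self.table[self.table["split"] == split].reset_index(drop=True),
            seed=self.seed,
        )

    @property
    def paths(self) -> list[str]:
        return list(self.table["path"])

    @classmethod
    def from_entries(cls, entries, seed: int | None = None) -> "DatasetManifest":
        """Build a manifest from (path, focal_index, z_step_um) triples."""
        rows = [
            {
                "path": str(p),
                "focal_index": int(fi),
                "z_step_um": float(zs),
                "split": "unassigned",
                "seed": -1 if seed is None else int(seed),
            }
            for p, fi, zs in entries
        ]
        return cls(pd.DataFrame(rows, columns=MANIFEST_COLUMNS), seed=seed)


def write_manifest(manifest: DatasetManifest, path: os.PathLike) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def read_manifest(path: os.PathLike) -> DatasetManifest:
    table = pd.read_csv(path, sep="\t")
    seeds = table["seed"].unique()
    seed = int(seeds[0]) if len(seeds) == 1 and seeds[0] >= 0 else None
    return DatasetManifest(table, seed=seed)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_dataset(
    manifest: DatasetManifest, train_fraction: float, seed: int
) -> DatasetManifest:
    """Randomly partition a dataset into train and test splits.

    The train count is ``round(train_fraction * N)`` with half rounded away
    from zero; membership is a seeded uniform permutation, so the result is
    reproducible from ``seed`` alone.
    """
    n = len(manifest)
    if n < 2:
        raise ValueError("need at least 2 stacks to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_train = _round_half_away(train_fraction * n)
    perm = np.random.default_rng(seed).permutation(n)
    split = np.array(["test"] * n, dtype=object)
    split[perm[:n_train]] = "train"
    table = manifest.table.copy()
    table["split"] = split
    table["seed"] = int(seed)
    return DatasetManifest(table, seed=seed)


# ---------------------------------------------------------------------------
# image primitives shared by training and inference


def _pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, Image) else np.asarray(image)


def crop(
    image,
    size: int,
    mode: str = "center",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Extract a ``size``×``size`` region (center-deterministic or random).

    Offsets are 0-based with floor division for centering; images smaller
    than the crop raise rather than pad.
    """
    px = _pixels(image)
    h, w = px.shape
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image shape {(h, w)}")
    if mode == "center":
        oy, ox = (h - size) // 2, (w - size) // 2
    elif mode == "random":
        if rng is None:
            raise ValueError("random crop requires an rng")
        oy = int(rng.integers(0, h - size + 1))
        ox = int(rng.integers(0, w - size + 1))
    else:
        raise ValueError(f"unknown crop mode {mode!r}")
    return px[oy : oy + size, ox : ox + size]


def downsample(image, factor: int) -> np.ndarray:
    """Reduce an image by an integer factor using the block mean.

    Trailing rows/columns that do not fill a full block are dropped.
    """
    px = _pixels(image)
    if int(factor) != factor or factor < 1:
        raise ValueError(f"downsampling factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return px.copy()
    h2, w2 = px.shape[0] // factor, px.shape[1] // factor
    if h2 < 1 or w2 < 1:
        raise ValueError("image too small for this downsampling factor")
    trimmed = px[: h2 * factor, : w2 * factor].astype(np.float32)
    return trimmed.reshape(h2, factor, w2, factor).mean(axis=(1, 3))


#: the 8 dihedral transforms as (n quarter-turns, horizontal flip) pairs
DIHEDRAL_ORDER: list[tuple[int, bool]] = [
    (k, f) for f in (False, True) for k in range(4)
]


def apply_dihedral(px: np.ndarray, element: int) -> np.ndarray:
    k, flip = DIHEDRAL_ORDER[element]
    out = np.rot90(px, k)
    return np.fliplr(out) if flip else out


def augment(image, rng: np.random.Generator) -> np.ndarray:
    """Apply one of the 8 square-symmetry transforms chosen uniformly.

    Flips and rotations leave the defocus label unchanged and wash out
    global illumination direction during training.
    """
    px = _pixels(image)
    if px.shape[0] != px.shape[1]:
        raise ValueError("augmentation requires a square image")
    return apply_dihedral(px, int(rng.integers(0, 8)))


def normalize(image) -> np.ndarray:
    """Per-image min–max normalization to [0, 1] (float32).

    This is part of the model contract: every image entering the network is
    normalized this way. A constant image maps to all zeros.
    """
    px = _pixels(image).astype(np.float32)
    lo, hi = float(px.min()), float(px.max())
    if hi <= lo:
        return np.zeros_like(px)
    return (px - lo) / (hi - lo)
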