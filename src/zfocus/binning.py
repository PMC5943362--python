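"""Discretization of the z-axis into labeled bins.

The autofocus network casts defocus estimation as classification: the z-axis
is cut into uniform bins and the network predicts a bin label, which is then
converted back to a z-position as the bin *center*.  A :class:`BinScheme` is a
closed lattice of centers ``lo, lo+width, ..., hi`` with half-open edges
``[c - width/2, c + width/2)``, so every covered z maps to exactly one label.

Reporting a bin center instead of a continuous value carries an irreducible
quantization error: for z uniform over the span the MSE floor is width²/12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BinScheme", "make_bins", "label_of", "center_of"]

#: tolerance for "exactly divisible" checks on micrometre grids
_GRID_EPS = 1e-9


@dataclass(frozen=True)
class BinScheme:
    """Uniform discretization of defocus values (µm) by bin centers."""

    lo: float
    hi: float
    width: float
    centers: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    def to_dict(self) -> dict:
        return {"z_lo_um": self.lo, "z_hi_um": self.hi, "bin_width_um": self.width}

    @classmethod
    def from_dict(cls, d: dict) -> "BinScheme":
        return make_bins(d["z_lo_um"], d["z_hi_um"], d["bin_width_um"])


def make_bins(lo: float, hi: float, width: float) -> BinScheme:
    """Build a bin scheme with centers on the closed lattice ``lo..hi``.

    Parameters
    ----------
    lo, hi : float
        Lowest and highest bin centers in µm.
    width : float
        Bin width in µm; ``hi - lo`` must be an integer multiple of it.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    ratio = (hi - lo) / width
    n_steps = round(ratio)
    if abs(ratio - n_steps) > _GRID_EPS * max(1.0, abs(ratio)) or n_steps < 1:
        nearest = (hi - lo) / max(1, n_steps)
        raise ValueError(
            f"span {hi - lo} µm is not divisible by bin width {width} µm; "
            f"nearest valid width is {nearest:g} µm"
        )
    centers = lo + width * np.arange(n_steps + 1)
    return BinScheme(lo=float(lo), hi=float(hi), width=float(width), centers=centers)


def label_of(scheme: BinScheme, z: float) -> int:
    """Label of the bin containing ``z``.

    Bins are half-open intervals ``[c - width/2, c + width/2)``; a z exactly
    on a boundary is assigned to the upper bin.
    """
    lo_edge = scheme.lo - scheme.width / 2
    hi_edge = scheme.hi + scheme.width / 2
    if not (lo_edge <= z < hi_edge):
        raise ValueError(
            f"z = {z} µm outside bin coverage [{lo_edge}, {hi_edge}) µm"
        )
    # guard against float fuzz right below a boundary (e.g. 2.4999999999)
    idx = math.floor((z - lo_edge) / scheme.width + _GRID_EPS)
    return min(idx, scheme.n_bins - 1)


def center_of(scheme: BinScheme, label: int) -> float:
    """z-position (µm) of the center of bin ``label``."""
    if not 0 <= label < scheme.n_bins:
        raise IndexError(f"label {label} out of range [0, {scheme.n_bins})")
    return float(scheme.centers[label])
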