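"""Classical focus scores and profile-based z-inference.

These are the passive software baselines the CNN is compared against: a
scalar "focus score" summarizes image sharpness, a *focus profile* is the
curve of that score versus z across a stack, and a z-estimate is obtained by
inverting a global averaged profile.  Three standard score families are
provided (the method set is pluggable):

``brenner``
    Brenner gradient: mean of squared 2-px horizontal and vertical intensity
    differences.
``edge_density``
    Mean gradient magnitude over "edge" pixels, with the edge threshold
    picked per-image by Otsu's method on the gradient-magnitude histogram.
``iqa_detail``
    Image-quality-assessment style detail content: the fraction of non-DC
    spectral energy in a mid/high spatial-frequency band.

All three depend only on intensity differences, so adding a constant offset
to an image leaves the score unchanged and a constant image scores 0.

Profile inversion inherits the two structural handicaps of any profile
method: the profile is even around its peak, so the *side* of focus must be
supplied externally, and the peak score varies from stack to stack, so the
per-stack maximum must be supplied for normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .zstack import ZStack, _pixels

__all__ = [
    "FOCUS_METHODS",
    "focus_score",
    "stack_profile",
    "FocusProfile",
    "build_global_profile",
    "ProfileEstimate",
    "infer_z_from_profile",
]


def _brenner(px: np.ndarray) -> float:
    dh = px[:, 2:] - px[:, :-2]
    dv = px[2:, :] - px[:-2, :]
    return float(np.mean(dh * dh) + np.mean(dv * dv))


def _otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's between-class-variance maximizer on a 1-D sample."""
    hist, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    w0 = cum_w / total
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = cum_m / cum_w
        m1 = (cum_m[-1] - cum_m) / (total - cum_w)
        between = w0 * w1 * (m0 - m1) ** 2
    between[~np.isfinite(between)] = -1.0
    return float(centers[int(np.argmax(between))])


def _edge_density(px: np.ndarray) -> float:
    gy, gx = np.gradient(px)
    mag = np.hypot(gx, gy)
    if mag.max() <= 0:
        return 0.0
    thresh = _otsu_threshold(mag.ravel())
    edges = mag[mag > thresh]
    if edges.size == 0:
        return 0.0
    return float(edges.mean())


def _iqa_detail(px: np.ndarray, band: tuple[float, float] = (0.05, 0.35)) -> float:
    if px.max() == px.min():
        return 0.0  # constant image; avoids ratios of round-off residuals
    # Hann window: the image is not periodic, so without tapering the FFT the
    # wrap-around discontinuity (e.g. from an illumination gradient) leaks
    # broadband energy and masks the true detail content
    wy = np.hanning(px.shape[0])[:, None]
    wx = np.hanning(px.shape[1])[None, :]
    spec = np.abs(np.fft.rfft2((px - px.mean()) * wy * wx)) ** 2
    fy = np.fft.fftfreq(px.shape[0])[:, None]
    fx = np.fft.rfftfreq(px.shape[1])[None, :]
    f = np.hypot(fy, fx)
    total = spec[f > 0].sum()
    if total <= 0:
        return 0.0
    lo, hi = band
    return float(spec[(f >= lo) & (f < hi)].sum() / total)


FOCUS_METHODS = {
    "brenner": _brenner,
    "edge_density": _edge_density,
    "iqa_detail": _iqa_detail,
}


def focus_score(image, method: str = "iqa_detail") -> float:
    """Scalar sharpness score ≥ 0 (higher = sharper) for one image."""
    try:
        fn = FOCUS_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown focus method {method!r}; choose from {sorted(FOCUS_METHODS)}"
        ) from None
    px = _pixels(image).astype(np.float64)
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise ValueError("focus scores need an image of at least 3x3 px")
    return fn(px)


def stack_profile(stack: ZStack, method: str = "iqa_detail") -> np.ndarray:
    """Score every slice; returns an array of (z_um, score) rows."""
    scores = [focus_score(stack.data[i], method) for i in range(stack.n_slices)]
    return np.column_stack([stack.z_positions, scores])


@dataclass(frozen=True)
class FocusProfile:
    """Averaged, max-normalized, peak-aligned score-vs-z curve."""

    z_offsets_um: np.ndarray   # peak aligned to 0
    scores: np.ndarray         # max exactly 1 at offset 0
    method: str
    n_stacks: int

    def __post_init__(self):
        peak = int(np.argmax(self.scores))
        if self.z_offsets_um[peak] != 0.0 or not np.isclose(self.scores[peak], 1.0):
            raise ValueError("profile must peak at offset 0 with score 1")

    def save(self, path) -> None:
        header = f"method={self.method} n_stacks={self.n_stacks}\nz_offset_um\tscore"
        np.savetxt(path, np.column_stack([self.z_offsets_um, self.scores]),
                   delimiter="\t", header=header)


def build_global_profile(stacks, method: str = "iqa_detail") -> FocusProfile:
    """Average per-stack profiles after max-normalization and peak alignment.

    Each stack's profile is divided by its own maximum and shifted so its
    peak sits at z = 0; profiles are then averaged pointwise on the common
    offset grid (offsets where every stack contributes).
    """
    stacks = list(stacks)
    if len(stacks) < 2:
        raise ValueError("need >= 2 stacks to build a global profile")
    step = stacks[0].z_step_um
    n = stacks[0].n_slices
    aligned = []
    for stack in stacks:
        if stack.n_slices != n or not np.isclose(stack.z_step_um, step):
            raise ValueError("all stacks must share one z-grid")
        prof = stack_profile(stack, method)
        scores = prof[:, 1] / prof[:, 1].max()
        aligned.append((int(np.argmax(scores)), scores))
    # common index offsets available in every aligned profile
    lo = -min(p for p, _ in aligned)
    hi = min(n - 1 - p for p, _ in aligned)
    offsets = np.arange(lo, hi + 1)
    mean_scores = np.mean(
        [scores[peak + offsets] for peak, scores in aligned], axis=0
    )
    # re-normalize: averaging can only keep the peak at 0 at exactly 1 if all
    # profiles peak there; enforce the profile invariants explicitly
    mean_scores /= mean_scores.max()
    peak = int(np.argmax(mean_scores))
    offsets = offsets - offsets[peak]
    return FocusProfile(
        z_offsets_um=offsets * step,
        scores=mean_scores,
        method=method,
        n_stacks=len(stacks),
    )


class ProfileEstimate(NamedTuple):
    z_um: float
    ambiguous: bool


def infer_z_from_profile(
    image,
    profile: FocusProfile,
    side: str,
    stack_max: float,
    method: str | None = None,
) -> ProfileEstimate:
    """Invert the global profile to estimate \\|z\\| on a known side of focus.

    The image's score is normalized by the externally supplied per-stack
    maximum (clipped to (0, 1]) and the requested half of the profile is
    searched, from the peak outward, for the z where the profile crosses that
    value (linear interpolation between samples).  If the half-profile is
    non-monotone and crosses more than once, the crossing nearest focus is
    returned and the estimate is flagged ambiguous.
    """
    if side not in ("above", "below"):
        raise ValueError("side must be 'above' or 'below'")
    if stack_max <= 0:
        raise ValueError("stack_max must be positive")
    score = focus_score(image, method or profile.method)
    s = min(score / stack_max, 1.0)
    sign = 1.0 if side == "above" else -1.0
    mask = sign * profile.z_offsets_um >= 0
    z_half = profile.z_offsets_um[mask] * sign   # 0 .. far, increasing
    s_half = profile.scores[mask]
    order = np.argsort(z_half)
    z_half, s_half = z_half[order], s_half[order]
    if s >= s_half[0]:
        return ProfileEstimate(0.0, False)
    crossings = []
    for i in range(len(z_half) - 1):
        a, b = s_half[i], s_half[i + 1]
        if (a >= s > b) or (a < s <= b):
            t = (s - a) / (b - a)
            crossings.append(z_half[i] + t * (z_half[i + 1] - z_half[i]))
    if not crossings:
        # score below the whole tail: clamp to the far end of coverage
        return ProfileEstimate(float(sign * z_half[-1]), True)
    return ProfileEstimate(float(sign * crossings[0]), len(crossings) > 1)
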