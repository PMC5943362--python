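"""Synthetic bright-field z-stacks with known ground-truth defocus.

The generator emulates the statistical structure of yeast cells growing in a
shallow microfluidic chamber imaged in bright field: round cells ~4–6 µm
across (~70–100 px at 60 nm/px), occasional PDMS support pillars, a gentle
illumination gradient, and additive sensor noise.  Each scene is frozen
across the stack (the same cells appear in every slice), and slices are
rendered at a series of signed defocus values.

Image formation is deliberately phenomenological rather than a rigorous
partially-coherent model.  Every object contributes two sharp component
maps — a narrow edge ring and a filled interior — that are Gaussian-blurred
with a width growing with \\|z\\| and weighted by two z-dependent contrast
terms:

* an edge term, strongest at focus and decaying as a Lorentzian in z (the
  crisp dark cell outline of an in-focus bright-field image);
* an interior term proportional to tanh(z / z_s), which *changes sign across
  focus*: cells appear bright-centered above the focal plane and
  dark-centered below it.

The sign asymmetry is mandatory: real bright-field images look measurably
different above vs. below focus, and the classifier can only learn the sign
of the defocus if the simulator reproduces that.  Blur is applied in the
frequency domain (periodic boundary), which makes the per-slice cost
independent of the blur width.

In two-population mode a fraction of cells sit on the chamber ceiling and
come into focus ``chamber_height_um`` above the floor population, which
reproduces the characteristic mixed-sharpness slices and bimodal network
outputs seen when cells occupy both surfaces.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .zstack import DatasetManifest, ZStack, write_manifest, write_zstack

__all__ = [
    "SceneConfig",
    "SceneSpec",
    "DefocusModel",
    "SceneRenderer",
    "generate_scene",
    "render_slice",
    "generate_zstack",
    "generate_dataset",
    "default_z_positions",
    "YEAST_PRESET",
    "EUGLENA_PRESET",
]


@dataclass(frozen=True)
class SceneConfig:
    """Ranges from which concrete scenes are drawn."""

    field_shape: tuple[int, int] = (600, 600)
    pixel_pitch_nm: float = 60.0
    # density chosen so a 256-px training/testing crop contains several cells
    # (~4-11), the typical per-crop content of a growing colony; a crop with
    # only one or two cells is the documented failure regime, not the norm
    n_cells_range: tuple[int, int] = (25, 60)
    cell_radius_um: tuple[float, float] = (2.0, 3.0)
    ceiling_fraction: float = 0.0
    chamber_height_um: float = 5.0
    pillars: bool = True
    pillar_radius_um: float = 5.0
    pillar_spacing_um: float = 50.0
    illum_gradient_max: float = 0.15
    noise_sd: float = 0.01


@dataclass(frozen=True)
class SceneSpec:
    """A concrete field of view: cell layout plus nuisance parameters."""

    field_shape: tuple[int, int]
    pixel_pitch_nm: float
    cells_xy: np.ndarray          # (n, 2) centers in px (x, y)
    cells_radius_um: np.ndarray   # (n,)
    cells_plane: np.ndarray       # (n,) 0 = floor, 1 = ceiling
    chamber_height_um: float
    pillars_xy: np.ndarray        # (m, 2) centers in px
    pillar_radius_um: float
    illum_gradient: tuple[float, float]   # relative slope across the field
    noise_sd: float

    @property
    def n_cells(self) -> int:
        return len(self.cells_radius_um)

    def px_per_um(self) -> float:
        return 1000.0 / self.pixel_pitch_nm

    def with_cells(self, xy, radius_um, plane) -> "SceneSpec":
        return dataclasses.replace(
            self,
            cells_xy=np.asarray(xy, dtype=float).reshape(-1, 2),
            cells_radius_um=np.asarray(radius_um, dtype=float),
            cells_plane=np.asarray(plane, dtype=int),
        )


@dataclass(frozen=True)
class DefocusModel:
    """How appearance depends on signed defocus z (µm).

    blur sigma(z) = sqrt(sigma0² + (slope·z)²) in px.  The ring (edge) term
    combines a dark in-focus outline decaying as 1/(1+(z/edge_halfwidth)²)
    with a smooth sign-asymmetric polarity component edge_flip_amp ·
    tanh(z/interior_scale): moving above focus the ring lightens and turns
    bright (the classic bright-field halo), below focus it stays dark.
    Interior contrast is amp·tanh(z/interior_scale), odd in z.  Together the
    two asymmetries make the two sides of focus distinguishable and keep the
    z → appearance map well separated within each side.
    """

    background: float = 0.5
    blur_sigma0_px: float = 0.8
    blur_slope_px_per_um: float = 2.5
    edge_amp: float = -0.55
    edge_halfwidth_um: float = 3.0
    edge_flip_amp: float = 0.18
    interior_amp: float = 0.35
    interior_scale_um: float = 2.0
    pillar_weight: float = 0.4
    z_range_um: float = 20.0

    def blur_sigma(self, z: float) -> float:
        return float(np.hypot(self.blur_sigma0_px, self.blur_slope_px_per_um * z))

    def edge_contrast(self, z: float) -> float:
        lorentz = self.edge_amp / (1.0 + (z / self.edge_halfwidth_um) ** 2)
        flip = self.edge_flip_amp * float(np.tanh(z / self.interior_scale_um))
        return lorentz + flip

    def interior_contrast(self, z: float) -> float:
        return self.interior_amp * float(np.tanh(z / self.interior_scale_um))


def generate_scene(config: SceneConfig, rng: np.random.Generator) -> SceneSpec:
    """Draw a concrete scene from the configured ranges (seeded)."""
    h, w = config.field_shape
    px_per_um = 1000.0 / config.pixel_pitch_nm
    max_r_px = config.cell_radius_um[1] * px_per_um
    if 2 * max_r_px > min(h, w):
        raise ValueError(
            f"cell diameter {2 * max_r_px:.0f} px exceeds field {config.field_shape}"
        )
    lo, hi = config.n_cells_range
    n = int(rng.integers(lo, hi + 1))
    xy = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    radius = rng.uniform(*config.cell_radius_um, n)
    plane = (rng.random(n) < config.ceiling_fraction).astype(int)

    pillars = np.zeros((0, 2))
    if config.pillars:
        spacing = config.pillar_spacing_um * px_per_um
        ox, oy = rng.uniform(0, spacing, 2)
        xs = np.arange(ox - spacing, w + spacing, spacing)
        ys = np.arange(oy - spacing, h + spacing, spacing)
        gx, gy = np.meshgrid(xs, ys)
        pillars = np.column_stack([gx.ravel(), gy.ravel()])
        margin = config.pillar_radius_um * px_per_um
        keep = (
            (pillars[:, 0] > -margin) & (pillars[:, 0] < w + margin)
            & (pillars[:, 1] > -margin) & (pillars[:, 1] < h + margin)
        )
        pillars = pillars[keep]

    theta = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0, config.illum_gradient_max)
    return SceneSpec(
        field_shape=config.field_shape,
        pixel_pitch_nm=config.pixel_pitch_nm,
        cells_xy=xy,
        cells_radius_um=radius,
        cells_plane=plane,
        chamber_height_um=config.chamber_height_um,
        pillars_xy=pillars,
        pillar_radius_um=config.pillar_radius_um,
        illum_gradient=(amp * np.cos(theta), amp * np.sin(theta)),
        noise_sd=config.noise_sd,
    )


# ---------------------------------------------------------------------------
# rendering


def _add_object(edge: np.ndarray, interior: np.ndarray, cx: float, cy: float,
                r_px: float, weight: float, edge_w: float = 1.5) -> None:
    """Accumulate one object's sharp ring and interior into the maps."""
    h, w = edge.shape
    pad = int(np.ceil(r_px + 6 * edge_w))
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    ring = np.exp(-0.5 * ((d - r_px) / edge_w) ** 2)
    disk = 1.0 / (1.0 + np.exp((d - r_px) / edge_w))
    edge[y0:y1, x0:x1] += weight * ring
    interior[y0:y1, x0:x1] += weight * disk


class SceneRenderer:
    """Renders slices of one frozen scene efficiently.

    The sharp component maps (per population) are built once; each slice
    multiplies their spectra by a Gaussian transfer function and inverse
    transforms, so rendering cost does not grow with blur width.  An optional
    sub-pixel translation is applied as a Fourier phase ramp (used by the
    closed-loop simulator to emulate lateral stage drift).
    """

    def __init__(self, scene: SceneSpec, model: DefocusModel | None = None):
        self.scene = scene
        self.model = model or DefocusModel()
        h, w = scene.field_shape
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.rfftfreq(w)[None, :]
        self._f2 = fy * fy + fx * fx
        self._fy, self._fx = fy, fx
        yy, xx = np.mgrid[0:h, 0:w]
        gx, gy = scene.illum_gradient
        self._illum = (1.0 + gx * (xx / w - 0.5) + gy * (yy / h - 0.5)).astype(
            np.float32
        )
        self._spectra = {}
        px_per_um = scene.px_per_um()
        for plane in (0, 1):
            sel = scene.cells_plane == plane
            if plane == 1 and not sel.any():
                continue
            edge = np.zeros(scene.field_shape)
            interior = np.zeros(scene.field_shape)
            for (cx, cy), r_um in zip(scene.cells_xy[sel],
                                      scene.cells_radius_um[sel]):
                _add_object(edge, interior, cx, cy, r_um * px_per_um, 1.0)
            if plane == 0:
                for cx, cy in scene.pillars_xy:
                    _add_object(edge, interior, cx, cy,
                                scene.pillar_radius_um * px_per_um,
                                self.model.pillar_weight)
            self._spectra[plane] = (np.fft.rfft2(edge), np.fft.rfft2(interior))

    def render(
        self,
        defocus_um: float,
        rng: np.random.Generator | None = None,
        shift_px: tuple[float, float] = (0.0, 0.0),
    ) -> np.ndarray:
        """One slice at signed defocus (µm); float32 in [0, 1].

        ``rng`` drives the additive noise; pass None (or noise_sd 0) for the
        deterministic noise-free part.
        """
        model, scene = self.model, self.scene
        if abs(defocus_um) > model.z_range_um + 1e-9:
            raise ValueError(
                f"|defocus| {abs(defocus_um)} µm outside validated range "
                f"±{model.z_range_um} µm"
            )
        h, w = scene.field_shape
        phase = 1.0
        if shift_px != (0.0, 0.0):
            sx, sy = shift_px
            phase = np.exp(-2j * np.pi * (self._fx * sx + self._fy * sy))
        signal = np.zeros(scene.field_shape)
        for plane, (edge_f, int_f) in self._spectra.items():
            z_eff = defocus_um - (scene.chamber_height_um if plane == 1 else 0.0)
            sigma = model.blur_sigma(z_eff)
            transfer = np.exp(-2.0 * np.pi**2 * sigma**2 * self._f2) * phase
            signal += model.edge_contrast(z_eff) * np.fft.irfft2(
                edge_f * transfer, s=(h, w)
            )
            signal += model.interior_contrast(z_eff) * np.fft.irfft2(
                int_f * transfer, s=(h, w)
            )
        img = model.background * self._illum * (1.0 + signal)
        if rng is not None and scene.noise_sd > 0:
            img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
        return np.clip(img, 0.0, 1.0).astype(np.float32)


def render_slice(
    scene: SceneSpec,
    defocus_um: float,
    model: DefocusModel | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Convenience one-shot renderer (builds a SceneRenderer internally)."""
    return SceneRenderer(scene, model).render(defocus_um, rng)


def default_z_positions(n_slices: int = 31, z_step_um: float = 1.0) -> np.ndarray:
    """Symmetric grid of n slices centred on focus (default 31 at Δz = 1 µm)."""
    if n_slices < 3 or n_slices % 2 == 0:
        raise ValueError("n_slices must be an odd number >= 3")
    half = n_slices // 2
    return (np.arange(n_slices) - half) * float(z_step_um)


def generate_zstack(
    scene: SceneSpec,
    z_positions,
    model: DefocusModel | None = None,
    rng: np.random.Generator | None = None,
    dtype=np.uint16,
) -> ZStack:
    """Render a full stack; the scene is identical at every z."""
    z = np.asarray(z_positions, dtype=float)
    if not np.all(np.diff(z) > 0):
        raise ValueError("z_positions must be strictly increasing")
    focal = np.flatnonzero(z == 0.0)
    if len(focal) != 1:
        raise ValueError("z_positions must contain 0 exactly once "
                         "(the annotated focal plane)")
    renderer = SceneRenderer(scene, model)
    slices = np.stack([renderer.render(zi, rng) for zi in z])
    if np.issubdtype(np.dtype(dtype), np.integer):
        top = np.iinfo(dtype).max
        slices = np.round(slices * top).astype(dtype)
    return ZStack(slices, z, int(focal[0]), scene.pixel_pitch_nm)


# -- dataset presets --------------------------------------------------------

#: 31 slices at Δz = 1 µm — the yeast acquisition geometry
YEAST_PRESET = {"n_slices": 31, "z_step_um": 1.0}
#: 51 slices at Δz = 12 µm — the large-cell, low-magnification variant
EUGLENA_PRESET = {"n_slices": 51, "z_step_um": 12.0}


def generate_dataset(
    n_stacks: int,
    out_dir,
    seed: int,
    scene_config: SceneConfig | None = None,
    model: DefocusModel | None = None,
    n_slices: int = 31,
    z_step_um: float = 1.0,
) -> DatasetManifest:
    """Write ``n_stacks`` stacks (fresh scene each) plus a manifest.

    Fully reproducible: all layouts and noise derive from ``seed``.
    Returns the manifest (also written to ``out_dir/manifest.tsv``).
    """
    if n_stacks < 2:
        raise ValueError("need at least 2 stacks (a dataset must be splittable)")
    scene_config = scene_config or SceneConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    z = default_z_positions(n_slices, z_step_um)
    entries = []
    root = np.random.SeedSequence(seed)
    for i, child in enumerate(root.spawn(n_stacks)):
        rng = np.random.default_rng(child)
        scene = generate_scene(scene_config, rng)
        stack = generate_zstack(scene, z, model, rng)
        path = out_dir / f"stack_{i:04d}.tif"
        write_zstack(stack, path)
        entries.append((str(path), stack.focal_index, stack.z_step_um))
    manifest = DatasetManifest.from_entries(entries, seed=seed)
    write_manifest(manifest, out_dir / "manifest.tsv")
    return manifest
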