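"""Synthetic scene generation and defocus rendering."""

import numpy as np
import pytest

from zfocus.focus_metrics import stack_profile
from zfocus.synth import (
    DefocusModel,
    SceneConfig,
    SceneRenderer,
    default_z_positions,
    generate_dataset,
    generate_scene,
    generate_zstack,
    render_slice,
)
from zfocus.zstack import read_zstack

SMALL = SceneConfig(field_shape=(128, 128), n_cells_range=(2, 4),
                    cell_radius_um=(1.2, 1.8), pillars=False, noise_sd=0.01)
SMALL_CLEAN = SceneConfig(field_shape=(128, 128), n_cells_range=(2, 4),
                          cell_radius_um=(1.2, 1.8), pillars=False, noise_sd=0.0)


def test_scene_generation_is_seeded():
    a = generate_scene(SMALL, np.random.default_rng(3))
    b = generate_scene(SMALL, np.random.default_rng(3))
    np.testing.assert_array_equal(a.cells_xy, b.cells_xy)
    np.testing.assert_array_equal(a.cells_radius_um, b.cells_radius_um)
    assert a.illum_gradient == b.illum_gradient


def test_cell_count_within_configured_range():
    for seed in range(10):
        scene = generate_scene(SMALL, np.random.default_rng(seed))
        assert 2 <= scene.n_cells <= 4


def test_two_population_fraction_is_binomial():
    """With ceiling fraction 0.5 roughly half of all cells sit on the ceiling."""
    config = SceneConfig(field_shape=(256, 256), n_cells_range=(10, 20),
                         ceiling_fraction=0.5, pillars=False)
    planes = np.concatenate([
        generate_scene(config, np.random.default_rng(s)).cells_plane
        for s in range(40)
    ])
    n, k = len(planes), planes.sum()
    # two-sided binomial check at ~4 sigma
    assert abs(k - n / 2) < 4 * np.sqrt(n * 0.25)


def test_empty_scene_renders_background_only():
    config = SceneConfig(field_shape=(128, 128), n_cells_range=(0, 0),
                         pillars=False, noise_sd=0.0, illum_gradient_max=0.0)
    scene = generate_scene(config, np.random.default_rng(0))
    img = render_slice(scene, 0.0)
    np.testing.assert_allclose(img, DefocusModel().background, atol=1e-5)


def test_impossible_geometry_raises():
    config = SceneConfig(field_shape=(32, 32), cell_radius_um=(2.0, 3.0))
    with pytest.raises(ValueError, match="exceeds field"):
        generate_scene(config, np.random.default_rng(0))


def test_above_and_below_focus_look_different():
    """Asymmetry invariant: +z and −z renders of one scene differ."""
    scene = generate_scene(SMALL_CLEAN, np.random.default_rng(5))
    renderer = SceneRenderer(scene)
    for z in (2.0, 5.0, 10.0):
        a, b = renderer.render(+z), renderer.render(-z)
        assert np.linalg.norm(a - b) > 1e-2 * a.size ** 0.5


def test_noise_free_rendering_is_deterministic():
    scene = generate_scene(SMALL_CLEAN, np.random.default_rng(6))
    np.testing.assert_array_equal(render_slice(scene, 3.0), render_slice(scene, 3.0))


def test_defocus_outside_validated_range_raises():
    scene = generate_scene(SMALL, np.random.default_rng(7))
    with pytest.raises(ValueError, match="validated range"):
        render_slice(scene, 25.0)


def test_focus_score_peaks_at_the_annotated_plane():
    """On noise-free stacks the detail measure is maximal at z = 0."""
    z = default_z_positions(13, 1.0)
    for seed in range(25):
        scene = generate_scene(SMALL_CLEAN, np.random.default_rng(100 + seed))
        stack = generate_zstack(scene, z, dtype=np.float32)
        prof = stack_profile(stack, "iqa_detail")
        assert prof[np.argmax(prof[:, 1]), 0] == 0.0


def test_two_population_focal_planes_are_chamber_height_apart():
    """Ceiling-only cells come into focus chamber_height above the floor."""
    config = SceneConfig(field_shape=(128, 128), n_cells_range=(3, 5),
                         cell_radius_um=(1.2, 1.8), ceiling_fraction=1.0,
                         chamber_height_um=5.0, pillars=False, noise_sd=0.0)
    z = default_z_positions(21, 1.0)
    for seed in range(5):
        scene = generate_scene(config, np.random.default_rng(seed))
        stack = generate_zstack(scene, z, dtype=np.float32)
        prof = stack_profile(stack, "iqa_detail")
        assert prof[np.argmax(prof[:, 1]), 0] == 5.0


def test_default_stack_geometry():
    """The yeast preset: 31 slices in 1 µm steps, focal slice in the middle."""
    z = default_z_positions()
    scene = generate_scene(SMALL, np.random.default_rng(8))
    stack = generate_zstack(scene, z, rng=np.random.default_rng(0))
    assert stack.n_slices == 31
    assert stack.z_step_um == 1.0
    assert stack.focal_index == 15
    assert stack.z_positions[0] == -15 and stack.z_positions[-1] == 15


def test_large_cell_variant_geometry():
    """The low-magnification variant: 51 slices in ~12 µm steps."""
    z = default_z_positions(51, 12.0)
    assert len(z) == 51 and z[1] - z[0] == 12.0
    model = DefocusModel(blur_slope_px_per_um=0.2, z_range_um=320.0)
    scene = generate_scene(SMALL, np.random.default_rng(9))
    stack = generate_zstack(scene, z, model=model, rng=np.random.default_rng(0))
    assert stack.n_slices == 51 and stack.focal_index == 25


def test_zstack_requires_the_focal_plane():
    scene = generate_scene(SMALL, np.random.default_rng(10))
    with pytest.raises(ValueError, match="contain 0"):
        generate_zstack(scene, [-1.0, 1.0, 2.0])


def test_minimal_three_slice_stack():
    scene = generate_scene(SMALL, np.random.default_rng(11))
    stack = generate_zstack(scene, [-1.0, 0.0, 1.0])
    assert stack.n_slices == 3 and stack.focal_index == 1


def test_dataset_generation_is_byte_reproducible(tmp_path):
    a = generate_dataset(3, tmp_path / "a", seed=7, scene_config=SMALL,
                         n_slices=5)
    b = generate_dataset(3, tmp_path / "b", seed=7, scene_config=SMALL,
                         n_slices=5)
    for pa, pb in zip(a.paths, b.paths):
        assert open(pa, "rb").read() == open(pb, "rb").read()
    sa = read_zstack(a.paths[1])
    assert sa.n_slices == 5
    c = generate_dataset(3, tmp_path / "c", seed=8, scene_config=SMALL,
                         n_slices=5)
    assert open(a.paths[0], "rb").read() != open(c.paths[0], "rb").read()


def test_dataset_requires_at_least_two_stacks(tmp_path):
    with pytest.raises(ValueError):
        generate_dataset(1, tmp_path, seed=0, scene_config=SMALL)
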