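"""Classical focus scores, profiles, and profile-based z-inference."""

import numpy as np
import pytest
from scipy import ndimage

from zfocus.focus_metrics import (
    FOCUS_METHODS,
    FocusProfile,
    build_global_profile,
    focus_score,
    infer_z_from_profile,
    stack_profile,
)
from zfocus.synth import (
    SceneConfig,
    default_z_positions,
    generate_scene,
    generate_zstack,
)
from zfocus.zstack import ZStack

CLEAN = SceneConfig(field_shape=(128, 128), n_cells_range=(2, 4),
                    cell_radius_um=(1.2, 1.8), pillars=False, noise_sd=0.0)


def _clean_stack(seed, n=13):
    scene = generate_scene(CLEAN, np.random.default_rng(seed))
    return generate_zstack(scene, default_z_positions(n, 1.0), dtype=np.float32)


@pytest.mark.parametrize("method", sorted(FOCUS_METHODS))
def test_constant_image_scores_zero(method):
    assert focus_score(np.full((32, 32), 0.7), method) == 0.0


@pytest.mark.parametrize("method", sorted(FOCUS_METHODS))
def test_scores_are_intensity_translation_invariant(method):
    img = np.random.default_rng(0).random((48, 48))
    a = focus_score(img, method)
    b = focus_score(img + 5.0, method)
    assert a == pytest.approx(b, rel=1e-9)
    assert a > 0  # strictly positive on a non-constant image


@pytest.mark.parametrize("method", sorted(FOCUS_METHODS))
def test_sharp_edge_scores_higher_than_blurred(method):
    img = np.zeros((64, 64))
    img[:, 32:] = 1.0
    blurred = ndimage.gaussian_filter(img, 4.0)
    assert focus_score(img, method) > focus_score(blurred, method)


def test_unknown_method_and_tiny_image_raise():
    with pytest.raises(ValueError, match="unknown focus method"):
        focus_score(np.zeros((8, 8)), "variance")
    with pytest.raises(ValueError, match="3x3"):
        focus_score(np.zeros((2, 8)), "brenner")


def test_stack_profile_has_one_score_per_slice():
    stack = _clean_stack(1)
    prof = stack_profile(stack, "iqa_detail")
    assert prof.shape == (stack.n_slices, 2)
    np.testing.assert_array_equal(prof[:, 0], stack.z_positions)


def test_profile_of_identical_slices_is_constant():
    img = np.random.default_rng(2).random((32, 32))
    stack = ZStack.from_step(np.stack([img] * 5), 2, 1.0)
    prof = stack_profile(stack, "brenner")
    np.testing.assert_allclose(prof[:, 1], prof[0, 1], rtol=1e-12)


def test_global_profile_of_identical_stacks_is_the_normalized_profile():
    stack = _clean_stack(3)
    profile = build_global_profile([stack, stack], "iqa_detail")
    raw = stack_profile(stack, "iqa_detail")[:, 1]
    np.testing.assert_allclose(profile.scores, raw / raw.max(), rtol=1e-9)
    assert profile.scores.max() == 1.0
    assert profile.z_offsets_um[np.argmax(profile.scores)] == 0.0
    assert profile.n_stacks == 2


def test_global_profile_aligns_different_peaks():
    """Stacks whose raw peaks sit at different indices are aligned before
    averaging, so the global profile still peaks at offset 0."""
    base = _clean_stack(4, n=13)  # peak at index 6
    scene = generate_scene(CLEAN, np.random.default_rng(40))
    off_center = generate_zstack(scene, np.arange(13) - 4.0,
                                 dtype=np.float32)  # peak at index 4
    profile = build_global_profile([base, off_center], "iqa_detail")
    assert profile.z_offsets_um[np.argmax(profile.scores)] == 0.0


def test_global_profile_unimodal_on_synthetic_stacks():
    """The averaged profile peaks at 0 and decays monotonically on each side
    (down to the flat noise floor far from focus)."""
    stacks = [_clean_stack(10 + s) for s in range(8)]
    profile = build_global_profile(stacks, "iqa_detail")
    peak = int(np.argmax(profile.scores))
    assert profile.z_offsets_um[peak] == 0.0
    assert np.all(np.diff(profile.scores[: peak + 1]) > -1e-3)
    assert np.all(np.diff(profile.scores[peak:]) < 1e-3)
    # strictly decreasing while the signal is well above the floor
    assert profile.scores[peak] > profile.scores[peak + 1] > profile.scores[peak + 2]
    assert profile.scores[peak] > profile.scores[peak - 1] > profile.scores[peak - 2]


def test_global_profile_input_validation():
    stack = _clean_stack(5)
    with pytest.raises(ValueError, match=">= 2 stacks"):
        build_global_profile([stack])
    other = _clean_stack(6, n=9)
    with pytest.raises(ValueError, match="one z-grid"):
        build_global_profile([stack, other])


def test_profile_inversion_recovers_slice_positions():
    """Inverting a stack's own profile returns each slice's |z| within half
    a grid step (exact at the stored samples).

    Checked over ±4 µm, where the profile is strictly monotone per side and
    inversion is well defined; farther out the score sits on the flat noise
    floor and carries no z information.
    """
    stack = _clean_stack(7, n=9)
    profile = build_global_profile([stack, stack], "iqa_detail")
    raw = stack_profile(stack, "iqa_detail")
    stack_max = raw[:, 1].max()
    for z, score in raw:
        side = "above" if z >= 0 else "below"
        est = infer_z_from_profile(stack.data[int(z - stack.z_positions[0])],
                                   profile, side, stack_max)
        assert abs(est.z_um - z) <= stack.z_step_um / 2 + 1e-6


def test_peak_score_maps_to_zero_on_either_side():
    stack = _clean_stack(8)
    profile = build_global_profile([stack, stack], "iqa_detail")
    focal = stack.data[stack.focal_index]
    stack_max = stack_profile(stack, "iqa_detail")[:, 1].max()
    assert infer_z_from_profile(focal, profile, "above", stack_max).z_um == 0.0
    assert infer_z_from_profile(focal, profile, "below", stack_max).z_um == 0.0


def test_nonmonotone_profile_flags_ambiguity():
    profile = FocusProfile(
        z_offsets_um=np.array([-2.0, -1.0, 0.0, 1.0, 2.0, 3.0]),
        scores=np.array([0.2, 0.6, 1.0, 0.4, 0.7, 0.1]),
        method="iqa_detail", n_stacks=2,
    )
    # score 0.5 crosses the bumpy upper side twice: nearest-to-focus, flagged
    img = np.random.default_rng(9).random((16, 16))
    score = focus_score(img, "iqa_detail")
    est = infer_z_from_profile(img, profile, "above", stack_max=score / 0.5)
    assert 0.0 < est.z_um < 1.0
    assert est.ambiguous


def test_inversion_input_validation():
    stack = _clean_stack(9)
    profile = build_global_profile([stack, stack], "iqa_detail")
    img = stack.data[0]
    with pytest.raises(ValueError, match="side"):
        infer_z_from_profile(img, profile, "left", 1.0)
    with pytest.raises(ValueError, match="stack_max"):
        infer_z_from_profile(img, profile, "above", 0.0)
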