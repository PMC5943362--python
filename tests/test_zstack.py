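"""Stack I/O, dataset splitting, and the image preprocessing primitives."""

import decimal

import numpy as np
import pytest

from zfocus.zstack import (
    DIHEDRAL_ORDER,
    DatasetManifest,
    Image,
    StackFormatError,
    ZStack,
    apply_dihedral,
    augment,
    crop,
    downsample,
    normalize,
    read_manifest,
    read_zstack,
    split_dataset,
    write_manifest,
    write_zstack,
)


def _random_stack(rng, n=5, side=32, step=1.0, focal=2):
    data = rng.integers(0, 2**16, size=(n, side, side), dtype=np.uint16)
    return ZStack.from_step(data, focal_index=focal, z_step_um=step)


# -- data model -------------------------------------------------------------


def test_z_positions_from_metadata():
    rng = np.random.default_rng(0)
    stack = _random_stack(rng, n=31, focal=15, step=1.0)
    assert stack.z_positions[0] == -15 and stack.z_positions[-1] == 15
    assert stack.z_positions[15] == 0

    stack = _random_stack(rng, n=3, focal=1, step=12.0)
    assert list(stack.z_positions) == [-12.0, 0.0, 12.0]


def test_invalid_stacks_rejected():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        ZStack.from_step(rng.random((1, 8, 8)), 0, 1.0)  # single slice
    with pytest.raises(ValueError):
        ZStack(rng.random((3, 8, 8)), [0.0, 1.0, 2.0], 1)  # z[focal] != 0
    with pytest.raises(ValueError):
        ZStack(rng.random((3, 8, 8)), [1.0, 0.0, -1.0], 1)  # not increasing


# -- I/O round trip ---------------------------------------------------------


def test_write_read_round_trip_is_bit_exact(tmp_path):
    stack = _random_stack(np.random.default_rng(1))
    path = tmp_path / "s.tif"
    write_zstack(stack, path)
    back = read_zstack(path)
    np.testing.assert_array_equal(back.data, stack.data)
    np.testing.assert_array_equal(back.z_positions, stack.z_positions)
    assert back.focal_index == stack.focal_index
    assert back.pixel_pitch_nm == stack.pixel_pitch_nm


def test_overwrite_replaces_existing_stack(tmp_path):
    rng = np.random.default_rng(2)
    path = tmp_path / "s.tif"
    write_zstack(_random_stack(rng), path)
    second = _random_stack(rng)
    write_zstack(second, path)
    np.testing.assert_array_equal(read_zstack(path).data, second.data)


def test_missing_metadata_is_a_format_error(tmp_path):
    stack = _random_stack(np.random.default_rng(3))
    path = tmp_path / "s.tif"
    write_zstack(stack, path)
    (tmp_path / "s.tif.meta.json").unlink()
    with pytest.raises(StackFormatError, match="metadata"):
        read_zstack(path)


def test_corrupt_metadata_is_a_format_error(tmp_path):
    stack = _random_stack(np.random.default_rng(3))
    path = tmp_path / "s.tif"
    write_zstack(stack, path)
    (tmp_path / "s.tif.meta.json").write_text("{not json")
    with pytest.raises(StackFormatError):
        read_zstack(path)


def test_manifest_round_trip(tmp_path):
    manifest = DatasetManifest.from_entries(
        [("a.tif", 15, 1.0), ("b.tif", 15, 1.0), ("c.tif", 14, 1.0)]
    )
    manifest = split_dataset(manifest, 0.8, seed=5)
    path = tmp_path / "manifest.tsv"
    write_manifest(manifest, path)
    back = read_manifest(path)
    assert back.table.equals(manifest.table)
    assert back.seed == 5


# -- splitting --------------------------------------------------------------


def _manifest_of(n):
    return DatasetManifest.from_entries([(f"s{i}.tif", 15, 1.0) for i in range(n)])


@pytest.mark.parametrize("n,frac,n_train,n_test", [(431, 0.8, 345, 86),
                                                   (136, 0.8, 109, 27)])
def test_reference_split_sizes(n, frac, n_train, n_test):
    split = split_dataset(_manifest_of(n), frac, seed=0)
    counts = split.table["split"].value_counts()
    assert counts["train"] == n_train and counts["test"] == n_test


def test_split_counts_follow_round_half_away_for_all_n():
    """Exhaustive check of the rounding rule against a decimal oracle."""
    for n in range(2, 1001):
        split = split_dataset(_manifest_of(n), 0.8, seed=1)
        expected = int(
            (decimal.Decimal(n) * decimal.Decimal("0.8")).quantize(
                0, rounding=decimal.ROUND_HALF_UP
            )
        )
        assert (split.table["split"] == "train").sum() == expected


def test_split_is_seeded_and_membership_varies():
    m = _manifest_of(10)
    a = split_dataset(m, 0.8, seed=1)
    b = split_dataset(m, 0.8, seed=1)
    c = split_dataset(m, 0.8, seed=2)
    assert a.table.equals(b.table)
    assert (a.table["split"] == "train").sum() == 8
    assert (c.table["split"] == "train").sum() == 8
    assert not a.table["split"].equals(c.table["split"])


def test_split_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        split_dataset(_manifest_of(1), 0.8, seed=0)
    with pytest.raises(ValueError):
        split_dataset(_manifest_of(10), 1.0, seed=0)


# -- crop -------------------------------------------------------------------


def test_center_crop_offsets_match_floor_formula():
    # full-camera geometry: 2080 x 1552 px, center 1000-px crop
    img = np.zeros((1552, 2080), dtype=np.uint8)
    img[276, 540] = 255  # expected top-left corner of the crop
    out = crop(img, 1000, mode="center")
    assert out.shape == (1000, 1000)
    assert out[0, 0] == 255


def test_crop_identity_and_errors():
    img = np.arange(64, dtype=np.float32).reshape(8, 8)
    np.testing.assert_array_equal(crop(img, 8), img)
    with pytest.raises(ValueError, match="exceeds"):
        crop(img, 9)


def test_random_crop_is_seeded_and_uniform():
    img = np.arange(100.0).reshape(10, 10)
    a = crop(img, 4, mode="random", rng=np.random.default_rng(9))
    b = crop(img, 4, mode="random", rng=np.random.default_rng(9))
    np.testing.assert_array_equal(a, b)
    # all 49 offsets reachable
    rng = np.random.default_rng(0)
    corners = {crop(img, 4, mode="random", rng=rng)[0, 0] for _ in range(2000)}
    assert len(corners) == 49


# -- downsample -------------------------------------------------------------


def test_downsample_shapes_and_identity():
    img = np.random.default_rng(0).random((1000, 1000))
    assert downsample(img, 4).shape == (250, 250)
    np.testing.assert_array_equal(downsample(img, 1), img)
    with pytest.raises(ValueError):
        downsample(img, 0)


def test_downsample_is_the_block_mean():
    img = np.arange(16.0).reshape(4, 4)
    out = downsample(img, 2)
    np.testing.assert_allclose(out, [[2.5, 4.5], [10.5, 12.5]])
    const = np.full((12, 12), 7.0)
    np.testing.assert_allclose(downsample(const, 3), np.full((4, 4), 7.0))


def test_downsample_then_replicate_preserves_block_means():
    rng = np.random.default_rng(4)
    img = rng.random((20, 20)).astype(np.float32)
    small = downsample(img, 4)
    up = np.kron(small, np.ones((4, 4), dtype=np.float32))
    np.testing.assert_allclose(downsample(up, 4), small, rtol=1e-6)


# -- augmentation -----------------------------------------------------------


def test_augment_requires_square_images():
    with pytest.raises(ValueError, match="square"):
        augment(np.zeros((4, 6)), np.random.default_rng(0))


def test_dihedral_transforms_permute_pixels():
    rng = np.random.default_rng(5)
    img = rng.random((9, 9))
    for element in range(8):
        out = apply_dihedral(img, element)
        np.testing.assert_array_equal(np.sort(out.ravel()), np.sort(img.ravel()))


def test_rot180_is_an_involution():
    img = np.random.default_rng(6).random((8, 8))
    rot180 = DIHEDRAL_ORDER.index((2, False))
    np.testing.assert_array_equal(
        apply_dihedral(apply_dihedral(img, rot180), rot180), img
    )


def test_augment_draws_all_eight_transforms_uniformly():
    """Chi-square on transform frequencies over 8000 seeded draws."""
    from scipy import stats

    # an image whose 8 dihedral variants are all distinct
    img = np.arange(16.0).reshape(4, 4)
    variants = {apply_dihedral(img, e).tobytes(): e for e in range(8)}
    assert len(variants) == 8
    rng = np.random.default_rng(12)
    counts = np.zeros(8)
    for _ in range(8000):
        counts[variants[augment(img, rng).tobytes()]] += 1
    chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=7)


# -- normalization ----------------------------------------------------------


def test_normalize_to_unit_range():
    img = np.array([[2.0, 4.0], [6.0, 10.0]])
    out = normalize(img)
    assert out.min() == 0.0 and out.max() == 1.0
    np.testing.assert_allclose(out, (img - 2) / 8)
    np.testing.assert_array_equal(normalize(np.full((3, 3), 5.0)), np.zeros((3, 3)))


def test_image_validates_shape_and_finiteness():
    with pytest.raises(ValueError):
        Image(np.zeros((0, 4)))
    with pytest.raises(ValueError):
        Image(np.array([[1.0, np.nan]]))
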