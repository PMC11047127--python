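"""NIfTI I/O round-trips and preprocessing transform rules."""

import numpy as np
import pytest

from afmsnet.volume_io import (DEFAULT_LABEL_REMAP, IOValidationError,
                               SplitSpec, VolumeRecord, central_crop,
                               dataset_split, gaussian_smooth,
                               low_label_filter, normalize, one_hot_and_fuse,
                               pad_to, read_volume, resample, write_volume)
from oracles import dense_gaussian_filter


def _record(rng, shape=(8, 8, 8), channels=1, with_labels=True):
    image = rng.normal(size=(*shape, channels)).astype(np.float32)
    labels = rng.integers(0, 3, size=shape) if with_labels else None
    return VolumeRecord(image=image, labels=labels, spacing=(1.0, 1.0, 1.0))


def test_nifti_round_trip_is_lossless(tmp_path, rng):
    rec = _record(rng)
    rec = VolumeRecord(image=rec.image, labels=rec.labels, spacing=(1.0, 1.5, 2.0))
    write_volume(rec, tmp_path / "img.nii.gz", tmp_path / "lab.nii.gz")
    back = read_volume(tmp_path / "img.nii.gz", tmp_path / "lab.nii.gz")
    assert np.array_equal(back.image, rec.image)
    assert np.array_equal(back.labels, rec.labels)
    assert back.spacing == pytest.approx(rec.spacing)


def test_nifti_multichannel_round_trip(tmp_path, rng):
    rec = _record(rng, channels=3, with_labels=False)
    write_volume(rec, tmp_path / "img.nii.gz")
    back = read_volume(tmp_path / "img.nii.gz")
    assert back.image.shape == (8, 8, 8, 3)
    assert np.array_equal(back.image, rec.image)


def test_read_missing_file_raises(tmp_path):
    with pytest.raises(Exception, match="no_such"):
        read_volume(tmp_path / "no_such.nii.gz")


# ---------------------------------------------------------------------------
# Crop / pad
# ---------------------------------------------------------------------------

def test_central_crop_even_and_odd_differences(rng):
    rec = _record(rng, shape=(24, 24, 24))
    out = central_crop(rec, (16, 16, 16))
    assert np.array_equal(out.image, rec.image[4:20, 4:20, 4:20])
    assert np.array_equal(out.labels, rec.labels[4:20, 4:20, 4:20])

    odd = _record(rng, shape=(25, 25, 25))
    out = central_crop(odd, (16, 16, 16))  # extra voxel dropped high side
    assert np.array_equal(out.image, odd.image[4:20, 4:20, 4:20])

    same = central_crop(rec, (24, 24, 24))
    assert np.array_equal(same.image, rec.image)
    with pytest.raises(IOValidationError):
        central_crop(rec, (32, 24, 24))


def test_crop_then_pad_restores_window(rng):
    rec = _record(rng, shape=(20, 20, 20))
    cropped = central_crop(rec, (12, 12, 12))
    restored = pad_to(cropped, (20, 20, 20))
    assert restored.shape == (20, 20, 20)
    assert np.array_equal(restored.image[4:16, 4:16, 4:16],
                          rec.image[4:16, 4:16, 4:16])


# ---------------------------------------------------------------------------
# Resample
# ---------------------------------------------------------------------------

def test_resample_identity_and_constant(rng):
    rec = _record(rng)
    out = resample(rec, target_spacing=(1.0, 1.0, 1.0))
    assert np.abs(out.image - rec.image).max() < 1e-6

    const = VolumeRecord(image=np.full((8, 8, 8, 1), 3.25))
    down = resample(const, target_shape=(5, 5, 5))
    assert np.abs(down.image - 3.25).max() < 1e-6
    assert down.spacing == pytest.approx((8 / 5, 8 / 5, 8 / 5))


def test_resample_linear_ramp_hits_closed_form(rng):
    # ramp along axis 0; endpoint-aligned sampling at i*(n-1)/(m-1)
    n, m = 9, 5
    ramp = np.broadcast_to(np.arange(n, dtype=float)[:, None, None],
                           (n, 4, 4)).copy()
    rec = VolumeRecord(image=ramp[..., None])
    out = resample(rec, target_shape=(m, 4, 4))
    want = np.arange(m) * (n - 1) / (m - 1)
    assert out.image[:, 0, 0, 0] == pytest.approx(want, abs=1e-6)


def test_resample_labels_stay_integer_and_label_safe(rng):
    rec = _record(rng, shape=(10, 10, 10))
    out = resample(rec, target_shape=(6, 6, 6))
    assert out.labels.dtype == rec.labels.dtype
    assert set(np.unique(out.labels)) <= set(np.unique(rec.labels))
    with pytest.raises(IOValidationError):
        resample(rec, target_spacing=(0.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# Intensity transforms
# ---------------------------------------------------------------------------

def test_normalize_zscores_the_nonzero_support(rng):
    image = rng.normal(loc=5.0, scale=2.0, size=(8, 8, 8, 1))
    image[:4] = 0.0  # background
    rec = VolumeRecord(image=image)
    out = normalize(rec)
    support = out.image[..., 0][image[..., 0] != 0]
    assert support.mean() == pytest.approx(0.0, abs=1e-5)
    assert support.std() == pytest.approx(1.0, abs=1e-5)
    assert np.all(out.image[..., 0][image[..., 0] == 0] == 0)
    again = normalize(out)
    assert np.abs(again.image - out.image).max() < 1e-5


def test_normalize_degenerate_channels_warn(rng):
    with pytest.warns(UserWarning):
        out = normalize(VolumeRecord(image=np.zeros((4, 4, 4, 1))))
    assert np.all(out.image == 0)
    with pytest.warns(UserWarning):
        out = normalize(VolumeRecord(image=np.full((4, 4, 4, 1), 7.0)))
    assert np.all(out.image == 0)


def test_gaussian_smooth_identity_constant_and_impulse(rng):
    rec = _record(rng)
    assert np.array_equal(gaussian_smooth(rec, 0.0).image, rec.image)

    const = VolumeRecord(image=np.full((8, 8, 8, 1), 2.0))
    assert np.abs(gaussian_smooth(const, 1.0).image - 2.0).max() < 1e-6

    impulse = np.zeros((9, 9, 9))
    impulse[4, 4, 4] = 1.0
    sm = gaussian_smooth(VolumeRecord(image=impulse[..., None]), 1.0)
    want = dense_gaussian_filter(impulse, 1.0)
    assert np.abs(sm.image[..., 0] - want).max() < 1e-6

    labels_rec = _record(rng)
    assert np.array_equal(gaussian_smooth(labels_rec, 1.0).labels,
                          labels_rec.labels)
    with pytest.raises(IOValidationError):
        gaussian_smooth(rec, -1.0)


# ---------------------------------------------------------------------------
# One-hot fusion, filtering, splitting
# ---------------------------------------------------------------------------

def test_one_hot_and_fuse_stacks_and_remaps(rng):
    mods = [VolumeRecord(image=rng.normal(size=(4, 4, 4, 1))) for _ in range(3)]
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[0, 0, 0] = 1
    labels[0, 0, 1] = 2
    labels[0, 0, 2] = 4
    image, one_hot = one_hot_and_fuse(mods, labels, n_classes=4)
    assert image.shape == (4, 4, 4, 3)
    assert np.array_equal(image[..., 1], mods[1].image[..., 0])
    assert one_hot.shape == (4, 4, 4, 4)
    assert one_hot[0, 0, 2, 3] == 1          # raw 4 -> channel 3
    assert np.all(one_hot.sum(axis=-1) == 1)


def test_one_hot_and_fuse_validation(rng):
    mods = [VolumeRecord(image=rng.normal(size=(4, 4, 4, 1))),
            VolumeRecord(image=rng.normal(size=(5, 4, 4, 1)))]
    with pytest.raises(IOValidationError):
        one_hot_and_fuse(mods, np.zeros((4, 4, 4), dtype=int), 4)
    good = [mods[0]]
    bad_labels = np.full((4, 4, 4), 9)
    with pytest.raises(IOValidationError):
        one_hot_and_fuse(good, bad_labels, 4)


def test_low_label_filter_boundary_behaviour():
    def with_foreground(n, total=4096):
        labels = np.zeros(total, dtype=int)
        labels[:n] = 1
        labels = labels.reshape(16, 16, 16)
        return VolumeRecord(image=np.zeros((16, 16, 16, 1)), labels=labels)

    sparse = with_foreground(15)           # 0.37 % -> discarded
    boundary = with_foreground(41)         # 41/4096 > 1 % -> kept
    full = with_foreground(4096)
    kept = low_label_filter([sparse, boundary, full])
    assert kept == [boundary, full]
    # exactly at the boundary: kept (strictly-less-than rule)
    frac_exact = VolumeRecord(image=np.zeros((10, 10, 10, 1)),
                              labels=(np.arange(1000) < 10).astype(int).reshape(10, 10, 10))
    assert low_label_filter([frac_exact]) == [frac_exact]


def test_dataset_split_sizes_and_determinism():
    ids = [f"v{i}" for i in range(10)]
    spec = SplitSpec(seed=4)
    tr, va, te = dataset_split(ids, spec)
    assert (len(tr), len(va), len(te)) == (8, 1, 1)
    assert sorted(tr + va + te) == sorted(ids)
    assert not (set(tr) & set(va)) and not (set(va) & set(te))
    assert dataset_split(ids, spec) == (tr, va, te)
    assert dataset_split(ids, SplitSpec(seed=5)) != (tr, va, te)

    tr2, va2, te2 = dataset_split(list(range(246)), SplitSpec(seed=0))
    # floor the 10% partitions, remainder goes to training
    assert (len(tr2), len(va2), len(te2)) == (198, 24, 24)
    with pytest.raises(IOValidationError):
        dataset_split(["a", "b"], spec)


def test_split_spec_validation():
    with pytest.raises(IOValidationError):
        SplitSpec(train=0.8, validation=0.3, test=0.1)
    with pytest.raises(IOValidationError):
        SplitSpec(train=-0.5, validation=1.0, test=0.5)
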