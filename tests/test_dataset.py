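"""Rotation augmentation, floor-grid patching, frame-disjoint splitting and
training normalization."""

import numpy as np
import pytest

from holophase.dataset import (
    DatasetManifest,
    NormalizationRange,
    PairedFrame,
    augment_rotations,
    denormalize,
    make_patches,
    normalize_for_training,
    size_ratio,
    split_frames,
    synthetic_patch_pairs,
)


def frame(h=512, w=256, fid="f0", seed=0):
    rng = np.random.default_rng(seed)
    return PairedFrame(hologram=rng.random((h, w)), phase=rng.uniform(-np.pi, np.pi, (h, w)),
                       frame_id=fid)


def camera_frames(n, h=1920, w=1200):
    # full camera-geometry frames; zero-copy constant content keeps 65 of
    # them cheap
    return [
        PairedFrame(hologram=np.broadcast_to(np.float64(i), (h, w)),
                    phase=np.broadcast_to(np.float64(0.1 * i), (h, w)),
                    frame_id=f"f{i:02d}")
        for i in range(n)
    ]


class TestAugmentRotations:
    def test_thirty_frames_grow_to_sixty_five(self):
        frames = [frame(128, 128, f"f{i}", i) for i in range(30)]
        out = augment_rotations(frames, 65, seed=1)
        assert len(out) == 65
        assert all(a is b for a, b in zip(out[:30], frames))  # originals preserved
        rotated = out[30:]
        assert all(f.rotation_applied in (90, 180) for f in rotated)
        assert len({f.frame_id for f in out}) == 65  # all distinct combinations

    def test_rotation_applied_jointly_and_180_twice_is_identity(self):
        f = frame(128, 128)
        out = augment_rotations([f], 2, seed=0)
        added = out[1]
        k = added.rotation_applied // 90
        assert np.array_equal(added.hologram, np.rot90(f.hologram, k))
        assert np.array_equal(added.phase, np.rot90(f.phase, k))
        assert np.array_equal(np.rot90(np.rot90(f.phase, 2), 2), f.phase)

    def test_noop_and_exhaustion(self):
        frames = [frame(128, 128, f"f{i}", i) for i in range(3)]
        assert all(a is b for a, b in zip(augment_rotations(frames, 3, seed=0), frames))
        with pytest.raises(ValueError, match="exhausted"):
            augment_rotations(frames, 10, seed=0)


class TestMakePatches:
    def test_camera_frame_yields_28_patches(self):
        patches = make_patches(camera_frames(1)[0])
        assert len(patches) == (1920 // 256) * (1200 // 256) == 28

    def test_single_patch_frames(self):
        assert len(make_patches(frame(256, 256))) == 1
        assert len(make_patches(frame(511, 256))) == 1  # remainder discarded

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            make_patches(frame(128, 300))

    def test_patches_tile_the_topleft_crop_exactly(self):
        f = frame(600, 520, seed=3)
        patches = make_patches(f)
        rebuilt = np.zeros((512, 512))
        for p in patches:
            i, j = p.grid_position
            rebuilt[i * 256 : (i + 1) * 256, j * 256 : (j + 1) * 256] = p.hologram_patch
        assert np.array_equal(rebuilt, f.hologram[:512, :512])

    def test_rotating_a_square_frame_rotates_its_patch(self):
        f = frame(256, 256, seed=4)
        rot = PairedFrame(hologram=np.rot90(f.hologram).copy(), phase=np.rot90(f.phase).copy(),
                          frame_id="r", rotation_applied=90)
        assert np.array_equal(
            make_patches(rot)[0].hologram_patch, np.rot90(make_patches(f)[0].hologram_patch)
        )


class TestSplitFrames:
    def test_paper_scale_split_counts(self):
        manifest = split_frames(camera_frames(65), validation_frames=11, seed=1)
        assert len(manifest.train) == 54 * 28 == 1512
        assert len(manifest.validation) == 11 * 28 == 308
        assert len(manifest.train) + len(manifest.validation) == 65 * 28 == 1820

    def test_split_is_frame_disjoint_and_deterministic(self):
        frames = [frame(512, 256, f"f{i}", i) for i in range(10)]
        m1 = split_frames(frames, 3, seed=5)
        m2 = split_frames(frames, 3, seed=5)
        assert m1.train == m2.train and m1.validation == m2.validation
        train_ids = {r["frame_id"] for r in m1.train}
        val_ids = {r["frame_id"] for r in m1.validation}
        assert train_ids.isdisjoint(val_ids)

    def test_manifest_json_round_trip(self):
        frames = [frame(512, 256, f"f{i}", i) for i in range(4)]
        m = split_frames(frames, 1, seed=2)
        back = DatasetManifest.from_json(m.to_json())
        assert back.train == m.train and back.validation == m.validation

    def test_degenerate_split_rejected(self):
        frames = [frame(256, 256, f"f{i}", i) for i in range(3)]
        with pytest.raises(ValueError):
            split_frames(frames, 3, seed=0)


class TestNormalization:
    def test_16bit_range_endpoints_map_exactly(self):
        rng = NormalizationRange.for_hologram("16")
        patch = np.array([[0.0, 65535.0]])
        assert np.allclose(normalize_for_training(patch, rng), [[-1.0, 1.0]])

    def test_round_trip(self):
        rng = NormalizationRange.for_phase()
        patch = np.random.default_rng(0).uniform(-np.pi, np.pi, (32, 32))
        back = denormalize(normalize_for_training(patch, rng), rng)
        assert np.allclose(back, patch, atol=1e-6)

    def test_phase_range_maps_to_unit_interval(self):
        rng = NormalizationRange.for_phase()
        assert normalize_for_training(np.array([[-np.pi]]), rng)[0, 0] == -1.0
        assert normalize_for_training(np.array([[np.pi]]), rng)[0, 0] == 1.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            NormalizationRange(1.0, 1.0)


def test_unet_dataset_ratio_rounds_to_16_2():
    assert size_ratio(24491, 1512) == 16.2


def test_synthetic_patch_pairs_are_normalized_and_seeded():
    x1, y1 = synthetic_patch_pairs(4, seed=9)
    x2, y2 = synthetic_patch_pairs(4, seed=9)
    assert x1.shape == y1.shape == (4, 64, 64)
    assert np.array_equal(x1, x2) and np.array_equal(y1, y2)
    assert x1.min() >= -1 and x1.max() <= 1 and y1.min() >= -1 and y1.max() <= 1
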