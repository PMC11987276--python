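import numpy as np
import pytest

from plusquant.segmentation import (
    SegmenterConfig,
    SegmenterModel,
    bf_score,
    clean_mask,
    detect_bifurcations,
    dice_score,
    sample_patches,
    split_patches,
    train_segmenter,
    tversky_index,
    TrainingPatch,
)
from plusquant.segmentation._nn import UNet
from plusquant.segmentation.train import _soft_tversky_batch


class TestDetectBifurcations:
    def test_straight_line_has_none(self):
        skel = np.zeros((20, 20), dtype=bool)
        skel[10, 2:18] = True
        assert detect_bifurcations(skel) == []

    def test_y_junction_found(self):
        skel = np.zeros((21, 21), dtype=bool)
        for i in range(10):
            skel[10, i] = True  # west arm
            skel[10 - 1 - i, 10 + 1 + i] = True  # NE arm
            skel[10 + 1 + i, 10 + 1 + i] = True  # SE arm
        skel[10, 10] = True
        found = detect_bifurcations(skel)
        assert (10, 10) in found

    def test_thick_input_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        with pytest.raises(ValueError, match="skeleton"):
            detect_bifurcations(mask)

    def test_matches_bruteforce_neighbor_count(self, phantom_default):
        from plusquant.morphometry import skeletonize_mask

        _, truth = phantom_default
        skel = skeletonize_mask(truth.mask)
        found = set(detect_bifurcations(skel))
        brute = set()
        rows, cols = np.nonzero(skel)
        for r, c in zip(rows, cols):
            n = skel[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2].sum() - 1
            if n >= 3:
                brute.add((r, c))
        assert found == brute


class TestSamplePatches:
    def _setup(self):
        img = np.random.default_rng(0).random((300, 300))
        mask = img > 0.5
        centers = [(r, c) for r in range(50, 260, 40) for c in range(50, 260, 40)]
        return img, mask, centers

    def test_exhaustive_sampling_uses_every_valid_center(self):
        img, mask, centers = self._setup()
        half = 64
        valid = [(r, c) for r, c in centers if half <= r <= 300 - half and half <= c <= 300 - half]
        patches = sample_patches(img, mask, centers, n=len(valid), size=128, seed=1)
        assert sorted(p.center for p in patches) == sorted(valid)

    def test_same_seed_same_patches(self):
        img, mask, centers = self._setup()
        a = sample_patches(img, mask, centers, n=5, size=128, seed=3)
        b = sample_patches(img, mask, centers, n=5, size=128, seed=3)
        assert [p.center for p in a] == [p.center for p in b]

    def test_window_convention(self):
        img = np.arange(128 * 128, dtype=float).reshape(128, 128)
        patches = sample_patches(img, img > 0, [(64, 64)], n=1, size=128, seed=0)
        assert np.array_equal(patches[0].image_patch, img)

    def test_no_valid_centers_raises(self):
        img, mask, _ = self._setup()
        with pytest.raises(ValueError, match="random vessel-pixel"):
            sample_patches(img, mask, [(5, 5)], n=1, size=128, seed=0)


class TestSplitPatches:
    @pytest.mark.parametrize("n,frac,expected", [(10, 0.8, (8, 2)), (5, 0.8, (4, 1))])
    def test_split_sizes(self, n, frac, expected):
        patches = [TrainingPatch(np.zeros((4, 4)), np.zeros((4, 4)), (0, 0))] * n
        train, val = split_patches(patches, frac, seed=0)
        assert (len(train), len(val)) == expected

    def test_deterministic_and_exhaustive(self):
        patches = [TrainingPatch(np.full((2, 2), i), np.zeros((2, 2)), (i, i)) for i in range(10)]
        t1, v1 = split_patches(patches, 0.8, seed=4)
        t2, v2 = split_patches(patches, 0.8, seed=4)
        assert [p.center for p in t1] == [p.center for p in t2]
        assert sorted(p.center for p in t1 + v1) == [(i, i) for i in range(10)]


class TestTverskyIndex:
    def test_identity_is_one(self):
        t = (np.random.default_rng(0).random((8, 8)) > 0.5).astype(float)
        assert tversky_index(t, t, 0.7, 0.3) == pytest.approx(1.0, abs=1e-6)

    def test_no_overlap_is_zero(self):
        t = np.ones((4, 4))
        assert tversky_index(np.zeros((4, 4)), t, 0.5, 0.5) == pytest.approx(0.0, abs=1e-9)

    def test_half_dice_toy_example(self):
        # TP=2, FN=2, FP=2 on a 3x3 pair
        target = np.array([[1, 1, 1], [1, 0, 0], [0, 0, 0]], dtype=float)
        pred = np.array([[1, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        assert tversky_index(pred, target, 0.5, 0.5) == pytest.approx(0.5, rel=1e-6)

    def test_equals_dice_at_half_weights(self, rng):
        for _ in range(50):
            a = (rng.random((8, 8)) > 0.5).astype(float)
            b = (rng.random((8, 8)) > 0.5).astype(float)
            inter = (a * b).sum()
            dice = 2 * inter / (a.sum() + b.sum()) if (a.sum() + b.sum()) else 1.0
            assert tversky_index(a, b, 0.5, 0.5) == pytest.approx(dice, abs=1e-7)

    def test_monotone_in_false_positives(self):
        target = np.zeros((6, 6))
        target[2:4, 2:4] = 1
        pred = target.copy()
        prev = tversky_index(pred, target, 0.7, 0.3)
        for extra in [(0, 0), (0, 1), (5, 5), (4, 0)]:
            pred[extra] = 1
            cur = tversky_index(pred, target, 0.7, 0.3)
            assert cur <= prev + 1e-12
            prev = cur

    def test_empty_empty_is_one(self):
        assert tversky_index(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0


class TestCleanMask:
    def test_blob_below_threshold_removed(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[1:11, 1:21] = True  # 200 px
        small = np.zeros_like(mask)
        small[25:28, 25:28] = True  # 9 px
        out = clean_mask(mask | small, min_area=200)
        assert np.array_equal(out, mask)

    def test_boundary_area_kept(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[0:10, 0:20] = True  # exactly 200
        assert np.array_equal(clean_mask(mask, 200), mask)
        mask199 = mask.copy()
        mask199[9, 19] = False
        assert not clean_mask(mask199, 200).any()

    def test_specks_removed_tree_intact(self, phantom_default):
        from scipy import ndimage

        _, truth = phantom_default
        rng = np.random.default_rng(1)
        noisy = truth.mask.copy()
        count = 0
        while count < 50:
            r, c = rng.integers(0, truth.mask.shape[0]), rng.integers(0, truth.mask.shape[1])
            patch = noisy[r : r + 2, c : c + 2]
            if patch.size == 4 and not noisy[max(0, r - 2) : r + 4, max(0, c - 2) : c + 4].any():
                patch[...] = True
                count += 1
        cleaned = clean_mask(noisy, 200)
        assert np.array_equal(cleaned, clean_mask(truth.mask, 200))

    def test_idempotent(self, phantom_default):
        _, truth = phantom_default
        once = clean_mask(truth.mask, 200)
        assert np.array_equal(clean_mask(once, 200), once)


class TestBFScore:
    def _square(self, shift=0):
        m = np.zeros((64, 64), dtype=bool)
        m[10 + shift : 25 + shift, 10 + shift : 25 + shift] = True
        return m

    def test_identity(self):
        assert bf_score(self._square(), self._square()) == 1.0

    def test_far_shift_scores_zero(self):
        # squares separated by 15 px, far beyond the 2-px tolerance
        assert bf_score(self._square(), self._square(shift=30), tolerance_px=2) == 0.0

    def test_one_px_dilation_within_tolerance(self):
        from scipy import ndimage

        truth = self._square()
        pred = ndimage.binary_dilation(truth)
        assert bf_score(pred, truth, tolerance_px=2) == 1.0

    def test_symmetry(self, rng):
        a = rng.random((32, 32)) > 0.6
        b = rng.random((32, 32)) > 0.6
        assert bf_score(a, b, 3) == pytest.approx(bf_score(b, a, 3))

    def test_both_empty(self):
        assert bf_score(np.zeros((8, 8)), np.zeros((8, 8))) == 1.0


class TestUNetTraining:
    """Small, fast training checks; full-scale convergence is covered by
    the acceptance suite."""

    def _tiny_patches(self, n=24, size=32, seed=0):
        rng = np.random.default_rng(seed)
        patches = []
        for _ in range(n):
            mask = np.zeros((size, size))
            r = rng.integers(4, size - 4)
            mask[r - 2 : r + 2, :] = 1.0
            img = 0.6 - 0.3 * mask + rng.normal(0, 0.05, (size, size))
            patches.append(TrainingPatch(np.clip(img, 0, 1), mask, (r, size // 2)))
        return patches

    def test_training_reduces_validation_loss(self):
        patches = self._tiny_patches()
        train, val = split_patches(patches, 0.8, seed=0)
        cfg = SegmenterConfig(depth=2, base_channels=4, epochs=6, seed=0, batch_size=4)
        model = train_segmenter(train, val, cfg)
        assert model.training_log[-1]["val_loss"] < model.training_log[0]["val_loss"]

    def test_all_empty_masks_rejected(self):
        patches = [
            TrainingPatch(np.random.rand(16, 16), np.zeros((16, 16)), (8, 8)) for _ in range(6)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            train_segmenter(patches[:4], patches[4:], SegmenterConfig(depth=2, base_channels=2, epochs=1))

    def test_retrain_reproduces_training_log(self):
        patches = self._tiny_patches()
        train, val = split_patches(patches, 0.8, seed=1)
        cfg = SegmenterConfig(depth=2, base_channels=4, epochs=3, seed=7, batch_size=4)
        log1 = train_segmenter(train, val, cfg).training_log
        log2 = train_segmenter(train, val, cfg).training_log
        assert log1 == log2

    def test_model_roundtrip_and_deterministic_prediction(self, tmp_path):
        patches = self._tiny_patches()
        train, val = split_patches(patches, 0.8, seed=2)
        cfg = SegmenterConfig(depth=2, base_channels=4, epochs=2, seed=3, batch_size=4)
        model = train_segmenter(train, val, cfg)
        model.save(tmp_path / "seg")
        loaded = SegmenterModel.load(tmp_path / "seg")
        x = np.random.default_rng(5).random((1, 1, 32, 32)).astype(np.float32)
        p1 = model.build_net().forward(x)
        p2 = loaded.build_net().forward(x)
        assert np.array_equal(p1, p2)


def test_unet_gradients_match_finite_differences():
    """Directional finite-difference check of the hand-written backprop.

    Biases are set to small nonzero values: with all-zero biases the
    zero-padded borders produce pre-activations exactly at the ReLU
    kink, where the subgradient choice and a central difference
    legitimately disagree.
    """
    net = UNet(depth=2, base=3, seed=1)
    rng = np.random.default_rng(0)
    # promote to float64 for a tight check
    convs = [l for blk in (net.enc + [net.bottleneck] + net.dec) for l in blk.layers if hasattr(l, "W")]
    convs.append(net.head)
    for lay in convs:
        lay.W = lay.W.astype(np.float64)
        lay.b = rng.normal(0.05, 0.02, lay.b.shape)
        lay.gW = np.zeros_like(lay.W)
        lay.gb = np.zeros_like(lay.b)
    x = rng.random((2, 1, 16, 16))
    t = (rng.random((2, 1, 16, 16)) > 0.7).astype(float)

    def forward64():
        h = x
        skips = []
        for blk, pool in zip(net.enc, net.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = net.bottleneck.forward(h)
        net._skip_ch = []
        for up, blk, skip in zip(net.ups, net.dec, reversed(skips)):
            h = up.forward(h)
            net._skip_ch.append(skip.shape[1])
            h = blk.forward(np.concatenate([skip, h], axis=1))
        return net.out_act.forward(net.head.forward(h))

    p = forward64()
    _, dl = _soft_tversky_batch(p, t, 0.7, 0.3)
    net.zero_grad()
    net.backward(dl)
    params = net.params()
    us = [rng.standard_normal(w.shape) for w, _ in params]
    analytic = sum(float((g * u).sum()) for (w, g), u in zip(params, us))
    eps = 1e-6
    for (w, _), u in zip(params, us):
        w += eps * u
    lp, _ = _soft_tversky_batch(forward64(), t, 0.7, 0.3)
    for (w, _), u in zip(params, us):
        w -= 2 * eps * u
    lm, _ = _soft_tversky_batch(forward64(), t, 0.7, 0.3)
    fd = (lp - lm) / (2 * eps)
    assert analytic == pytest.approx(fd, rel=1e-3)
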