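import numpy as np
import pytest

from lycheevision.core import Circle, Region
from lycheevision.synthetic import SceneSpec, generate_scene, render_training_patches
from lycheevision.texture_filter import (
    N_BINS,
    LBPFeature,
    TrainedClassifier,
    extract_patch,
    filter_detections,
    hik,
    hik_gram,
    size_gate,
    train,
    uniform_lbp,
    uniform_code_table,
)


def feature(bins):
    hist = np.zeros(N_BINS)
    hist[: len(bins)] = bins
    return LBPFeature(hist / hist.sum() if hist.sum() else hist)


def mixed_regime_features(seed, n_pos, n_neg):
    regimes = ("well", "weak", "overexposed")
    pos, neg = [], []
    per_p, per_n = -(-n_pos // 3), -(-n_neg // 3)
    for i, regime in enumerate(regimes):
        spec = SceneSpec(
            seed=seed + 1000 * i, n_fruits=5, cluster_prob=0.0, occluder_prob=0.0,
            n_distractors=2, illumination=regime,
        )
        p, n = render_training_patches(spec, per_p, per_n)
        pos += [uniform_lbp(x) for x in p]
        neg += [uniform_lbp(x) for x in n]
    return pos[:n_pos], neg[:n_neg]


class TestUniformCodeTable:
    def test_exactly_58_uniform_codes(self):
        # independent enumeration: count circular bit transitions per code
        def transitions(code):
            bits = [(code >> k) & 1 for k in range(8)]
            return sum(bits[k] != bits[(k + 1) % 8] for k in range(8))

        uniform = [c for c in range(256) if transitions(c) <= 2]
        assert len(uniform) == 58
        table = uniform_code_table()
        assert table.shape == (256,)
        assert len(set(table[uniform])) == 58
        nonuniform = [c for c in range(256) if transitions(c) > 2]
        assert all(table[c] == N_BINS - 1 for c in nonuniform)


class TestUniformLBP:
    def test_constant_patch_single_bin(self):
        feat = uniform_lbp(np.full((8, 8), 50.0))
        assert feat.histogram.sum() == pytest.approx(1.0)
        # strictly-greater bits: constant neighbors give the all-zero code
        assert feat.histogram[uniform_code_table()[0]] == pytest.approx(1.0)

    def test_step_edge_all_uniform(self):
        patch = np.zeros((10, 10))
        patch[:, 5:] = 100.0
        feat = uniform_lbp(patch)
        assert feat.histogram[N_BINS - 1] == pytest.approx(0.0)

    def test_checkerboard_nonuniform_half(self):
        # two-level checkerboard: low-center pixels see alternating
        # brighter edge neighbors -> 10101010-type non-uniform codes;
        # high-center pixels have no strictly greater neighbor -> the
        # all-zero uniform code. Interior parity split is exactly half.
        patch = np.indices((10, 10)).sum(axis=0) % 2 * 100.0
        feat = uniform_lbp(patch)
        assert feat.histogram[N_BINS - 1] == pytest.approx(0.5)
        assert feat.histogram[uniform_code_table()[0]] == pytest.approx(0.5)

    def test_enumeration_oracle(self, rng):
        # brute-force per-pixel code computation on a small random patch
        patch = rng.integers(0, 256, (7, 7)).astype(float)
        offsets = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
        table = uniform_code_table()
        ref = np.zeros(N_BINS)
        for y in range(1, 6):
            for x in range(1, 6):
                code = 0
                for bit, (dy, dx) in enumerate(offsets):
                    if patch[y + dy, x + dx] > patch[y, x]:
                        code |= 1 << bit
                ref[table[code]] += 1
        ref /= ref.sum()
        np.testing.assert_allclose(uniform_lbp(patch).histogram, ref, atol=1e-12)

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError):
            uniform_lbp(np.ones((2, 5)))

    def test_normalized_sums_to_one(self, rng):
        feat = uniform_lbp(rng.integers(0, 256, (16, 16)).astype(float))
        assert feat.histogram.sum() == pytest.approx(1.0, abs=1e-9)


class TestHIK:
    def test_self_similarity_is_one(self, rng):
        hist = rng.random(N_BINS)
        f = LBPFeature(hist / hist.sum())
        assert hik(f, f) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        f1 = feature([1, 0, 0])
        f2 = feature([0, 1, 1])
        assert hik(f1, f2) == 0.0

    def test_direct_arithmetic(self):
        f1 = feature([0.5, 0.5, 0.0])
        f2 = feature([0.25, 0.25, 0.5])
        assert hik(f1, f2) == pytest.approx(0.5)

    def test_symmetry_and_upper_bound(self, rng):
        for _ in range(20):
            a = rng.random(N_BINS)
            b = rng.random(N_BINS)
            fa, fb = LBPFeature(a / a.sum()), LBPFeature(b / b.sum())
            k = hik(fa, fb)
            assert k == pytest.approx(hik(fb, fa))
            assert k <= 1.0 + 1e-12
            if k == pytest.approx(1.0, abs=1e-12):
                np.testing.assert_allclose(fa.histogram, fb.histogram)

    def test_gram_positive_semidefinite(self, rng):
        feats = [LBPFeature(h / h.sum()) for h in rng.random((25, N_BINS))]
        gram = hik_gram(feats, feats)
        eigvals = np.linalg.eigvalsh(gram)
        assert eigvals.min() >= -1e-8


class TestSizeGate:
    @staticmethod
    def _region(area):
        return Region(
            label=1, mask=np.ones((1, area), bool), offset=(0, 0), area=area,
            centroid=(0.0, 0.0), boundary=np.zeros((0, 2)),
        )

    def test_inclusive_bounds(self):
        regions = [self._region(a) for a in (799, 800, 1700, 1701)]
        kept = size_gate(regions, 800, 1700)
        assert [r.area for r in kept] == [800, 1700]

    def test_empty_list(self):
        assert size_gate([], 800, 1700) == []

    def test_all_within_is_identity(self):
        regions = [self._region(a) for a in (900, 1200, 1500)]
        assert size_gate(regions) == regions

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            size_gate([], 100, 100)


class TestExtractPatch:
    def test_uniform_image_uniform_patch(self):
        img = np.full((60, 60, 3), 90, np.uint8)
        patch = extract_patch(img, Circle(30, 30, 12))
        assert patch.shape == (32, 32)
        assert patch.std() <= 1.0

    def test_corner_circle_clamped(self):
        img = np.full((60, 60, 3), 90, np.uint8)
        patch = extract_patch(img, Circle(1, 1, 15))
        assert patch.shape == (32, 32)

    def test_fully_outside_is_error(self):
        img = np.zeros((30, 30, 3), np.uint8)
        with pytest.raises(ValueError):
            extract_patch(img, Circle(100, 100, 5))

    def test_patch_mean_tracks_source(self):
        img, gt = generate_scene(SceneSpec(seed=11, n_fruits=3, cluster_prob=0.0,
                                           occluder_prob=0.0))
        c = gt.fruits[0].circle
        patch = extract_patch(img, c)
        x0, x1 = int(c.cx - c.r), int(c.cx + c.r) + 1
        y0, y1 = int(c.cy - c.r), int(c.cy + c.r) + 1
        src_gray = img[y0:y1, x0:x1].astype(float) @ np.array([0.2125, 0.7154, 0.0721])
        assert patch.mean() == pytest.approx(src_gray.mean(), rel=0.05)


class TestTrainAndPersistence:
    def test_separable_toy_problem(self):
        pos = [feature([1, 0, 0]) for _ in range(10)]
        neg = [feature([0, 1, 0]) for _ in range(10)]
        clf = train(pos, neg)
        assert all(clf.predict(f) == 1 for f in pos)
        assert all(clf.predict(f) == -1 for f in neg)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            train([feature([1])], [])

    def test_degenerate_identical_classes_flagged(self, rng):
        feats = [LBPFeature(h / h.sum()) for h in rng.random((10, N_BINS))]
        try:
            clf = train(feats, list(feats))
        except ValueError:
            return
        acc = np.mean(
            [clf.predict(f) == 1 for f in feats] + [clf.predict(f) == -1 for f in feats]
        )
        assert acc <= 0.5 + 1e-9

    def test_heldout_accuracy(self):
        pos_tr, neg_tr = mixed_regime_features(900, 100, 100)
        pos_te, neg_te = mixed_regime_features(5900, 50, 50)
        clf = train(pos_tr, neg_tr)
        acc = np.mean(
            [clf.predict(f) == 1 for f in pos_te]
            + [clf.predict(f) == -1 for f in neg_te]
        )
        assert acc >= 0.90

    def test_save_load_bit_identical(self, rng, tmp_path):
        pos, neg = mixed_regime_features(31, 20, 20)
        clf = train(pos, neg)
        path = tmp_path / "model.json"
        clf.save(path)
        clf2 = TrainedClassifier.load(path)
        probes = [LBPFeature(h / h.sum()) for h in rng.random((20, N_BINS))]
        for f in probes:
            assert clf.decision(f) == clf2.decision(f)  # exact, not approx


@pytest.fixture(scope="module")
def classifier():
    pos, neg = mixed_regime_features(900, 90, 90)
    return train(pos, neg)


class TestFilterDetections:

    def test_fruit_detections_kept(self, classifier):
        img, gt = generate_scene(SceneSpec(seed=77, n_fruits=6, cluster_prob=0.0,
                                           occluder_prob=0.0))
        dets = [f.circle for f in gt.fruits]
        accepted, rejected = filter_detections(dets, img, classifier)
        assert len(rejected) <= 0.1 * len(dets)

    def test_background_detections_rejected(self, classifier):
        img, gt = generate_scene(SceneSpec(seed=78, n_fruits=2, cluster_prob=0.0,
                                           occluder_prob=0.0, width=400, height=300))
        rng = np.random.default_rng(5)
        dets = []
        while len(dets) < 10:
            c = Circle(rng.uniform(20, 380), rng.uniform(20, 280), rng.uniform(16, 22))
            if all(
                np.hypot(c.cx - f.circle.cx, c.cy - f.circle.cy) > c.r + f.circle.r
                for f in gt.fruits
            ):
                dets.append(c)
        accepted, rejected = filter_detections(dets, img, classifier)
        assert len(accepted) <= 0.1 * len(dets)

    def test_empty_detections(self, classifier):
        img = np.zeros((40, 40, 3), np.uint8)
        assert filter_detections([], img, classifier) == ([], [])
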