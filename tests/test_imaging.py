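"""FOV geometry, kNN pixel classification and coverage estimation."""

import numpy as np
import pytest

from phenopine.imaging import (
    BACKGROUND,
    SEEDLING,
    CoverageEstimate,
    FovGeometry,
    PixelTrainingSet,
    circle_mask,
    classify_pixels,
    coverage_fractions,
    estimate_coverage,
    fov_radius_cm,
    train_pixel_classifier,
)
from phenopine.synthetic import SceneTruth, generate_seedling_image


class TestFovRadius:
    def test_study_geometry_gives_5_3_cm(self):
        assert round(fov_radius_cm(24.0, 25.0), 1) == 5.3

    def test_zero_angle(self):
        assert fov_radius_cm(10.0, 0.0) == 0.0

    def test_right_angle_cone(self):
        assert fov_radius_cm(10.0, 90.0) == pytest.approx(10.0)

    @pytest.mark.parametrize("d,a", [(-1.0, 25.0), (0.0, 25.0), (24.0, 180.0), (24.0, -5.0)])
    def test_invalid_geometry_rejected(self, d, a):
        with pytest.raises(ValueError):
            fov_radius_cm(d, a)


def toy_training_set():
    feats = np.array([
        [0.0, 0.0, 0.0], [0.05, 0.05, 0.05],        # near-black background
        [0.2, 0.6, 0.2], [0.25, 0.55, 0.2],          # green seedling
    ])
    labels = np.array([BACKGROUND, BACKGROUND, SEEDLING, SEEDLING])
    return PixelTrainingSet(feats, labels)


class TestClassifier:
    def test_k1_reproduces_training_labels(self):
        train = toy_training_set()
        clf = train_pixel_classifier(train, k=1)
        assert list(clf.predict(train.features)) == list(train.labels)

    def test_query_near_black_cluster(self):
        clf = train_pixel_classifier(toy_training_set(), k=3)
        assert clf.predict(np.array([[0.02, 0.02, 0.02]]))[0] == BACKGROUND

    def test_majority_vote_matches_brute_force(self, rng):
        feats = rng.uniform(0, 1, size=(9, 3))
        labels = np.array([SEEDLING, BACKGROUND] * 4 + [SEEDLING])
        train = PixelTrainingSet(feats, labels)
        clf = train_pixel_classifier(train, k=3)
        for _ in range(20):
            q = rng.uniform(0, 1, size=3)
            d = np.linalg.norm(feats - q, axis=1)
            nearest = labels[np.argsort(d)[:3]]
            expected = SEEDLING if (nearest == SEEDLING).sum() >= 2 else BACKGROUND
            assert clf.predict(q[None, :])[0] == expected

    def test_training_order_permutation_invariant(self, rng):
        feats = rng.uniform(0, 1, size=(40, 3))
        labels = np.where(feats[:, 1] > 0.5, SEEDLING, BACKGROUND)
        queries = rng.uniform(0, 1, size=(50, 3))
        base = train_pixel_classifier(PixelTrainingSet(feats, labels), k=5).predict(queries)
        perm = rng.permutation(40)
        shuffled = train_pixel_classifier(
            PixelTrainingSet(feats[perm], labels[perm]), k=5
        ).predict(queries)
        assert list(base) == list(shuffled)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            PixelTrainingSet(np.zeros((3, 3)), np.array([BACKGROUND] * 3))

    @pytest.mark.parametrize("k", [0, 2, -3])
    def test_even_or_nonpositive_k_rejected(self, k):
        with pytest.raises(ValueError, match="odd"):
            train_pixel_classifier(toy_training_set(), k=k)

    def test_channel_mismatch_rejected(self):
        clf = train_pixel_classifier(toy_training_set(), k=1)
        with pytest.raises(ValueError, match="channels"):
            clf.predict(np.zeros((2, 4)))


class TestCoverageFractions:
    geometry = FovGeometry(pixels_per_cm=10.0 / fov_radius_cm(24.0, 25.0),
                           center_px=(16.0, 16.0))  # radius exactly 10 px

    def test_all_seedling(self):
        mask = np.ones((33, 33), dtype=bool)
        est = coverage_fractions(mask, self.geometry)
        assert (est.c_seedling, est.c_background) == (1.0, 0.0)

    def test_all_background(self):
        est = coverage_fractions(np.zeros((33, 33), dtype=bool), self.geometry)
        assert (est.c_seedling, est.c_background) == (0.0, 1.0)

    def test_half_disk_by_direct_count(self):
        # centre on a half-pixel: reflection symmetry makes the split exact
        geom = FovGeometry(pixels_per_cm=10.0 / fov_radius_cm(24.0, 25.0),
                           center_px=(16.5, 16.5))
        mask = np.zeros((34, 34), dtype=bool)
        mask[:17, :] = True  # upper half-plane through the centre
        est = coverage_fractions(mask, geom)
        inside = circle_mask((34, 34), (16.5, 16.5), geom.radius_px)
        direct = mask[inside].sum() / inside.sum()
        assert est.c_seedling == pytest.approx(direct)
        assert est.c_seedling == pytest.approx(0.5, abs=1.0 / inside.sum())

    def test_invariant_to_pixels_outside_circle(self):
        mask = np.zeros((33, 33), dtype=bool)
        mask[:16, :] = True
        base = coverage_fractions(mask, self.geometry).c_seedling
        mask2 = mask.copy()
        mask2[0, :] = ~mask2[0, :]  # row far outside the radius-10 circle
        assert coverage_fractions(mask2, self.geometry).c_seedling == base

    def test_circle_outside_image_rejected(self):
        geom = FovGeometry(pixels_per_cm=1.0, center_px=(-100.0, -100.0))
        with pytest.raises(ValueError, match="circle"):
            coverage_fractions(np.zeros((10, 10), dtype=bool), geom)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CoverageEstimate(0.7, 0.7, 100)


class TestSceneRoundTrip:
    def geometry_for(self, scene: SceneTruth) -> FovGeometry:
        return FovGeometry(
            pixels_per_cm=scene.fov_radius / fov_radius_cm(24.0, 25.0),
            center_px=scene.fov_center,
        )

    @pytest.mark.parametrize("coverage", [0.0, 0.25, 0.5, 0.8, 1.0])
    def test_mask_coverage_matches_truth(self, coverage):
        scene = SceneTruth(coverage, seed=7)
        _, mask = generate_seedling_image(scene)
        est = coverage_fractions(mask, self.geometry_for(scene))
        assert abs(est.c_seedling - coverage) <= 1.0 / est.n_pixels_in_circle

    def test_classifier_recovers_truth_on_separable_colors(self, rng):
        scene = SceneTruth(0.6, seed=11)
        img, mask = generate_seedling_image(scene)
        n = 300
        fg = np.stack([rng.integers(30, 70, n), rng.integers(100, 170, n),
                       rng.integers(30, 80, n)], axis=1) / 255.0
        bg = rng.integers(2, 22, size=(n, 3)) / 255.0
        train = PixelTrainingSet(
            np.vstack([fg, bg]), np.array([SEEDLING] * n + [BACKGROUND] * n)
        )
        clf = train_pixel_classifier(train, k=5)
        geom = self.geometry_for(scene)
        est = estimate_coverage(img, clf, geom)
        truth = coverage_fractions(mask, geom)
        assert est.c_seedling == pytest.approx(truth.c_seedling, abs=1e-12)

    def test_saturated_scenes_classify_exactly(self):
        img, mask = generate_seedling_image(SceneTruth(1.0, seed=3))
        assert mask.sum() > 0
        labels = classify_pixels(
            img, train_pixel_classifier(toy_training_set(), k=1)
        )
        inside = circle_mask(mask.shape, (48.0, 48.0), 40.0)
        assert np.all(labels[inside] == SEEDLING)

    def test_circle_must_fit_image(self):
        with pytest.raises(ValueError, match="fit"):
            SceneTruth(0.5, image_size=(20, 20), fov_center=(10.0, 10.0),
                       fov_radius=40.0)
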