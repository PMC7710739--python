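import numpy as np
import pytest

from tmedyn import imaging
from tmedyn.io import CohortError
from tmedyn.simulate import simulate_histology_image


@pytest.fixture(scope="module")
def classifier():
    return imaging.train_default_classifier(seed=0, n_images=4)


@pytest.fixture(scope="module")
def sample_image():
    return simulate_histology_image(500, 500, 25, 10, seed=8)


def synthetic_disk_image(area=100, size=300, intensity=40):
    """Single dark disk of a target pixel area on a light background."""
    image = np.full((size, size), 210, dtype=np.uint8)
    radius = np.sqrt(area / np.pi)
    yy, xx = np.mgrid[:size, :size]
    mask = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2
    image[mask] = intensity
    return np.repeat(image[:, :, None], 3, axis=2), mask.sum()


class TestSegmentation:
    def test_blank_image_gives_no_candidates(self):
        image, _ = simulate_histology_image(400, 400, 0, 0, seed=1)
        # tissue-only image: texture is below Otsu contrast for nuclei,
        # but slide vs tissue still separates; nuclei-sized components
        # must not appear
        candidates = imaging.segment_nuclei(image)
        assert candidates == []

    def test_uniform_image_gives_no_candidates(self):
        image = np.full((200, 200, 3), 128, dtype=np.uint8)
        assert imaging.segment_nuclei(image) == []

    def test_single_disk_detected_with_area(self):
        image, true_area = synthetic_disk_image(area=100)
        candidates = imaging.segment_nuclei(image)
        assert len(candidates) == 1
        assert abs(candidates[0].area - true_area) / true_area < 0.15

    def test_failure_region_blob_discarded(self):
        image, _ = synthetic_disk_image(area=2500)
        assert imaging.segment_nuclei(image) == []

    def test_min_shape_filter(self):
        image, _ = synthetic_disk_image(area=20)
        assert imaging.segment_nuclei(image) == []


class TestFeatures:
    def test_identical_cells_get_identical_features(self):
        image = np.full((300, 600), 210, dtype=np.uint8)
        yy, xx = np.mgrid[:300, :600]
        for cx in (150, 450):
            image[(yy - 150) ** 2 + (xx - cx) ** 2 <= 36] = 40
        rgb = np.repeat(image[:, :, None], 3, axis=2)
        candidates = imaging.segment_nuclei(rgb)
        feats = imaging.extract_features(candidates, rgb)
        assert len(candidates) == 2
        assert np.allclose(feats[0], feats[1], atol=1e-9)

    def test_brightness_change_leaves_shape_features(self):
        image, _ = synthetic_disk_image(area=120, intensity=40)
        darker = image.copy()
        darker[darker == 210] = 180  # brighten/darken background & contrast
        c1 = imaging.segment_nuclei(image)
        c2 = imaging.segment_nuclei(darker)
        f1 = imaging.extract_features(c1, image)
        f2 = imaging.extract_features(c2, darker)
        n_shape = len(imaging.FEATURE_NAMES) - 24
        assert np.allclose(f1[0][:n_shape], f2[0][:n_shape], rtol=1e-6)
        assert not np.allclose(f1[0][n_shape:], f2[0][n_shape:])

    def test_area_feature_matches_component_pixels(self):
        image, _ = synthetic_disk_image(area=110)
        candidates = imaging.segment_nuclei(image)
        feats = imaging.extract_features(candidates, image)
        assert feats[0][imaging.FEATURE_NAMES.index("area")] == candidates[0].area

    def test_candidate_outside_image_errors(self):
        image, _ = synthetic_disk_image()
        bad = imaging.CellCandidate(x=1e6, y=1e6, area=100)
        with pytest.raises(CohortError):
            imaging.extract_features([bad], image)


class TestClassifier:
    def test_separable_clouds_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.2, (30, 36))
        b = rng.normal(5, 0.2, (30, 36))
        feats = np.vstack([a, b])
        labels = ["lymphocyte"] * 30 + ["other"] * 30
        model = imaging.train_classifier(feats, labels, seed=0)
        assert (model.predict(feats) == np.array(labels)).all()

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(0, 1, (120, 36))
        labels = ["lymphocyte"] * 60 + ["other"] * 60
        rng.shuffle(labels)
        from sklearn.model_selection import cross_val_score

        model = imaging.train_classifier(feats, labels, seed=0)
        acc = cross_val_score(model, feats, labels, cv=5).mean()
        assert abs(acc - 0.5) <= 0.12

    def test_probabilities_valid(self, classifier, sample_image):
        image, _ = sample_image
        candidates = imaging.segment_nuclei(image)
        imaging.extract_features(candidates, image)
        imaging.classify_candidates(candidates, classifier)
        probs = np.array([c.probability for c in candidates])
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_single_class_errors(self):
        feats = np.zeros((20, 36))
        with pytest.raises(CohortError):
            imaging.train_classifier(feats, ["lymphocyte"] * 20)


class TestFilters:
    def make(self, prob, area, label="lymphocyte"):
        c = imaging.CellCandidate(x=0, y=0, area=area)
        c.probability = prob
        c.label = label
        return c

    def test_high_prob_in_gate_is_lymphocyte(self):
        lymph, _, _ = imaging.filter_lymphocytes([self.make(0.98, 100)])
        assert len(lymph) == 1

    def test_size_gate_excludes(self):
        lymph, _, _ = imaging.filter_lymphocytes([self.make(0.98, 160)])
        assert lymph == []

    def test_dead_zone(self):
        lymph, non, _ = imaging.filter_lymphocytes([self.make(0.5, 100)])
        assert lymph == [] and non == []

    def test_low_prob_is_non_lymphocyte(self):
        _, non, _ = imaging.filter_lymphocytes([self.make(0.05, 300, label="other")])
        assert len(non) == 1

    def test_large_cells_use_q3_of_big_areas(self):
        cells = [self.make(0.05, a, label="other") for a in (250, 300, 350, 400)]
        _, _, large = imaging.filter_lymphocytes(cells)
        q3 = np.quantile([250, 300, 350, 400], 0.75)
        assert sorted(c.area for c in large) == [a for a in (250, 300, 350, 400) if a >= q3]

    def test_raising_cutoff_never_increases_count(self, classifier, sample_image):
        image, _ = sample_image
        candidates = imaging.segment_nuclei(image)
        imaging.extract_features(candidates, image)
        imaging.classify_candidates(candidates, classifier)
        counts = [
            len(imaging.filter_lymphocytes(candidates, prob_min=cut)[0])
            for cut in (0.5, 0.8, 0.9, 0.97, 0.99)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestTiling:
    def test_small_image_matches_untiled(self, sample_image):
        image, _ = sample_image
        tiled = imaging.tile_process(image, tile_size=2050)
        untiled = imaging.segment_nuclei(image)
        assert len(tiled) == len(untiled)
        a = sorted((round(c.x), round(c.y)) for c in tiled)
        b = sorted((round(c.x), round(c.y)) for c in untiled)
        assert a == b

    def test_global_coordinates_reconstructed(self):
        # one disk placed inside tile (1,1) of a 2-tile x 2-tile image
        size, tile = 600, 300
        image = np.full((size, size), 210, dtype=np.uint8)
        yy, xx = np.mgrid[:size, :size]
        cx = cy = 450  # local (150,150) within tile (1,1)
        image[(yy - cy) ** 2 + (xx - cx) ** 2 <= 36] = 40
        rgb = np.repeat(image[:, :, None], 3, axis=2)
        found = imaging.tile_process(rgb, tile_size=tile)
        assert len(found) == 1
        assert found[0].x == pytest.approx(cx, abs=1.0)
        assert found[0].y == pytest.approx(cy, abs=1.0)

    def test_planted_cells_across_tiles_recovered(self):
        image, truth = simulate_histology_image(800, 800, 60, 20, seed=12)
        found = imaging.tile_process(image, tile_size=400)
        assert abs(len(found) - len(truth)) <= 5

    def test_whole_tile_shift_translates_centroids(self):
        tile = 200
        base = np.full((tile * 2, tile * 2), 210, dtype=np.uint8)
        yy, xx = np.mgrid[: tile * 2, : tile * 2]
        base[(yy - 100) ** 2 + (xx - 100) ** 2 <= 36] = 40
        shifted = np.full_like(base, 210)
        shifted[tile:, tile:] = base[:tile, :tile]
        rgb = lambda a: np.repeat(a[:, :, None], 3, axis=2)
        c0 = imaging.tile_process(rgb(base), tile_size=tile)
        c1 = imaging.tile_process(rgb(shifted), tile_size=tile)
        assert len(c0) == len(c1) == 1
        assert c1[0].x - c0[0].x == pytest.approx(tile, abs=1e-6)
        assert c1[0].y - c0[0].y == pytest.approx(tile, abs=1e-6)


class TestDensity:
    def test_zero_lymphocytes_zero_density(self, sample_image):
        image, _ = sample_image
        quant = imaging.compute_density(0, image)
        assert quant.density_per_mm2 == 0.0

    def test_unit_arithmetic(self):
        dark = np.zeros((2000, 2000, 3), dtype=np.uint8)  # all tissue
        quant = imaging.compute_density(50, dark, um_per_px=0.5)
        assert quant.tissue_area_mm2 == pytest.approx(1.0)
        assert quant.density_per_mm2 == pytest.approx(50.0)

    def test_halving_um_per_px_quarters_area(self):
        dark = np.zeros((1000, 1000, 3), dtype=np.uint8)
        a = imaging.compute_density(10, dark, um_per_px=0.5)
        b = imaging.compute_density(10, dark, um_per_px=0.25)
        assert b.tissue_area_mm2 == pytest.approx(a.tissue_area_mm2 / 4)
        assert b.density_per_mm2 == pytest.approx(4 * a.density_per_mm2)

    def test_white_image_zero_tissue_errors(self):
        white = np.full((100, 100, 3), 255, dtype=np.uint8)
        with pytest.raises(CohortError):
            imaging.compute_density(1, white)


class TestEndToEnd:
    def test_planted_count_recovery_single_image(self, classifier):
        image, truth = simulate_histology_image(700, 700, 60, 20, seed=33)
        candidates = imaging.tile_process(image, classifier)
        lymph, _, _ = imaging.filter_lymphocytes(candidates)
        planted = int((truth.cell_type == "lymphocyte").sum())
        assert abs(len(lymph) - planted) / planted < 0.10
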