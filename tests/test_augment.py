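"""Rotation/flip/elastic transforms and training-set arithmetic."""

import numpy as np
import pytest

from bladderseg.augment import (
    AugmentationScenario,
    ScenarioError,
    augment_case,
    build_training_set,
    elastic_case,
    rotate_case,
)


@pytest.fixture(scope="module")
def tiny_pair():
    """A small random (image, labels) pair for counting tests."""
    rng = np.random.default_rng(0)
    image = rng.normal(size=(16, 16, 8)).astype(np.float32)
    labels = rng.choice([0, 125, 255], size=(16, 16, 8)).astype(np.uint8)
    return image, labels


@pytest.fixture(scope="module")
def phantom_pair(noiseless_case):
    """Noiseless phantom at the model's working resolution."""
    from bladderseg.prep import preprocess_case

    volume, masks = noiseless_case
    image, labels = preprocess_case(volume, masks, target=(128, 128, 32))
    return image, labels.labels


class TestScenario:
    def test_composition_must_sum_to_na(self):
        with pytest.raises(ScenarioError):
            AugmentationScenario(na=10, n_pos_rot=3, n_neg_rot=3, n_elastic=3,
                                 flip_assignment=(False,) * 6)

    @pytest.mark.parametrize("na,n_rot,n_elastic", [(5, 3, 2), (10, 6, 4)])
    def test_shipped_compositions(self, na, n_rot, n_elastic):
        sc = AugmentationScenario.for_na(na)
        assert sc.n_pos_rot + sc.n_neg_rot == n_rot
        assert sc.n_elastic == n_elastic
        assert sc.n_pos_rot + sc.n_neg_rot + sc.n_elastic == na

    def test_unknown_na_rejected(self):
        with pytest.raises(ScenarioError):
            AugmentationScenario.for_na(7)


class TestRotate:
    def test_zero_angle_is_identity(self, tiny_pair):
        image, labels = tiny_pair
        img, lab = rotate_case(image, labels, 0.0)
        np.testing.assert_array_equal(img, image)
        np.testing.assert_array_equal(lab, labels)

    def test_flip_is_an_involution(self, tiny_pair):
        image, labels = tiny_pair
        img, lab = rotate_case(*rotate_case(image, labels, 0.0, flip=True),
                               0.0, flip=True)
        np.testing.assert_array_equal(img, image)
        np.testing.assert_array_equal(lab, labels)

    def test_rotation_near_inverse(self, phantom_pair):
        image, labels = phantom_pair
        img, lab = rotate_case(image, labels, 7.0)
        _, back = rotate_case(img, lab, -7.0)
        fg = labels != 0
        agree = (back[fg] == labels[fg]).mean()
        assert agree >= 0.95

    def test_label_set_preserved(self, phantom_pair):
        _, labels = phantom_pair
        _, lab = rotate_case(np.zeros_like(labels, dtype=float), labels, 8.3,
                             flip=True)
        assert set(np.unique(lab)) <= {0, 125, 255}


class TestElastic:
    def test_zero_alpha_is_identity(self, tiny_pair):
        image, labels = tiny_pair
        img, lab = elastic_case(image, labels, np.random.default_rng(1),
                                alpha=0.0)
        np.testing.assert_array_equal(img, image)
        np.testing.assert_array_equal(lab, labels)

    def test_same_seed_same_warp(self, phantom_pair):
        image, labels = phantom_pair
        a = elastic_case(image, labels, np.random.default_rng(5))
        b = elastic_case(image, labels, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    @pytest.mark.parametrize("seed", [0, 5, 8])
    def test_class_volumes_nearly_preserved(self, phantom_pair, seed):
        image, labels = phantom_pair
        _, lab = elastic_case(image, labels, np.random.default_rng(seed))
        for value in (125, 255):
            before = (labels == value).sum()
            after = (lab == value).sum()
            assert abs(after - before) / before < 0.10

    def test_negative_sigma_rejected(self, tiny_pair):
        with pytest.raises(ValueError):
            elastic_case(*tiny_pair, np.random.default_rng(0), sigma=0.0)


class TestAugmentCase:
    @pytest.mark.parametrize("na", [5, 10])
    def test_emits_exactly_na_pairs(self, tiny_pair, na):
        image, labels = tiny_pair
        out = augment_case(image, labels, AugmentationScenario.for_na(na, seed=2))
        assert len(out) == na
        for img, lab in out:
            assert img.shape == image.shape
            assert set(np.unique(lab)) <= {0, 125, 255}

    def test_geometric_consistency_marker(self, phantom_pair):
        # transform the wall mask both as "image" and as labels: the warped
        # intensity support must land on the warped label support
        _, labels = phantom_pair
        image = (labels == 255).astype(np.float32)
        img, lab = rotate_case(image, labels, 9.0, flip=True)
        wall = lab == 255
        assert wall.sum() > 0
        assert (img[wall] > 0.25).mean() > 0.9


class TestBuildTrainingSet:
    @pytest.mark.parametrize("x,na,n_train", [(7, 5, 42), (7, 10, 77),
                                              (14, 5, 84)])
    def test_table_arithmetic(self, tiny_pair, x, na, n_train):
        image, labels = tiny_pair
        cases = [(image, labels)] * x
        train, val = build_training_set(cases,
                                        AugmentationScenario.for_na(na, seed=1))
        assert len(train) == n_train  # x + x * na
        assert len(val) == x  # one extra augmentation per original

    def test_deterministic_in_seed(self, tiny_pair):
        image, labels = tiny_pair
        sc = AugmentationScenario.for_na(5, seed=4)
        t1, v1 = build_training_set([(image, labels)], sc)
        t2, v2 = build_training_set([(image, labels)], sc)
        for (a, _), (b, _) in zip(t1 + v1, t2 + v2):
            np.testing.assert_array_equal(a, b)

    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError):
            build_training_set([], AugmentationScenario.for_na(5))
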