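"""Dice metric oracles, bilateral post-processing and the experiment driver."""

import numpy as np
import pytest

from bladderseg.posteval import (
    DiceReport,
    bilateral_filter_probs,
    binarize,
    dice,
    evaluate_case,
    postprocess,
)
from bladderseg.prep import LabelVolume


def dice_bruteforce(a, b):
    """Voxel-loop oracle for 2|A∩B| / (|A| + |B|)."""
    inter = na = nb = 0
    for idx in np.ndindex(a.shape):
        av, bv = bool(a[idx]), bool(b[idx])
        inter += av and bv
        na += av
        nb += bv
    return 1.0 if na + nb == 0 else 2.0 * inter / (na + nb)


class TestDice:
    def test_agrees_with_bruteforce_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(0.05, 0.6)
            a = rng.random((8, 8, 4)) < p
            b = rng.random((8, 8, 4)) < p
            assert dice(a, b) == pytest.approx(dice_bruteforce(a, b))

    def test_hand_counted_example(self):
        a = np.zeros((4, 4, 1), dtype=bool)
        b = np.zeros((4, 4, 1), dtype=bool)
        a[0, :4, 0] = True  # |A| = 4
        b[0, 1:4, 0] = True  # overlap 3
        b[1, :3, 0] = True  # |B| = 6
        assert dice(a, b) == pytest.approx(2 * 3 / (4 + 6))  # 0.6

    def test_identity_and_disjoint(self):
        a = np.zeros((5, 5, 2), dtype=bool)
        a[1:3, 1:3, :] = True
        b = np.zeros_like(a)
        b[4, 4, :] = True
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0

    def test_both_empty_is_perfect_agreement(self):
        z = np.zeros((3, 3, 2), dtype=bool)
        assert dice(z, z) == 1.0
        assert dice(z, ~z) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


class TestBilateralFilter:
    def test_constant_probmap_unchanged(self):
        probs = np.stack([np.full((16, 16, 4), v) for v in (0.2, 0.3, 0.5)],
                         axis=-1)
        out = bilateral_filter_probs(probs)
        np.testing.assert_allclose(out, probs, atol=1e-6)

    def test_isolated_spike_attenuated(self):
        probs = np.zeros((21, 21, 1, 3))
        probs[..., 0] = 1.0
        probs[10, 10, 0] = (0.0, 1.0, 0.0)  # lone wall-class voxel
        out = bilateral_filter_probs(probs)
        assert out[10, 10, 0, 1] < 0.5

    def test_plateau_interior_preserved(self):
        probs = np.zeros((30, 30, 1, 3))
        probs[..., 0] = 1.0
        probs[5:25, 5:25, 0] = (0.0, 1.0, 0.0)
        out = bilateral_filter_probs(probs)
        assert (out[12:18, 12:18, 0, 1] >= 0.9).all()

    def test_channels_renormalized(self):
        rng = np.random.default_rng(1)
        raw = rng.random((10, 10, 2, 3))
        probs = raw / raw.sum(-1, keepdims=True)
        out = bilateral_filter_probs(probs)
        np.testing.assert_allclose(out.sum(-1), 1.0, atol=1e-9)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            bilateral_filter_probs(np.zeros((4, 4, 1, 3)), sigma_spatial=0)


class TestBinarize:
    def test_argmax_selects_wall(self):
        probs = np.array([[[[0.1, 0.7, 0.2]]]])
        assert binarize(probs).labels[0, 0, 0] == 255

    def test_exact_tie_resolves_to_background(self):
        probs = np.full((1, 1, 1, 3), 1.0 / 3.0)
        assert binarize(probs).labels[0, 0, 0] == 0

    def test_idempotent_on_hard_labels(self):
        rng = np.random.default_rng(2)
        labels = rng.choice([0, 125, 255], size=(6, 6, 3)).astype(np.uint8)
        onehot = LabelVolume(labels).onehot
        np.testing.assert_array_equal(binarize(onehot).labels, labels)

    def test_postprocess_preserves_shape_and_label_set(self):
        rng = np.random.default_rng(3)
        raw = rng.random((16, 16, 4, 3))
        probs = raw / raw.sum(-1, keepdims=True)
        out = postprocess(probs)
        assert out.labels.shape == (16, 16, 4)
        assert set(np.unique(out.labels)) <= {0, 125, 255}


class TestPostprocessCeiling:
    def test_memorized_prediction_survives_postprocessing(self, noiseless_case):
        """The probability map of a fully memorized model (correct classes
        at high confidence) keeps overall Dice >= 0.95 through the bilateral
        filter and binarization — post-processing must not damage a good
        prediction, including the few-voxel tumor blob."""
        from bladderseg.prep import preprocess_case

        volume, masks = noiseless_case
        _, labels = preprocess_case(volume, masks, target=(64, 64, 16))
        rng = np.random.default_rng(0)
        probs = labels.onehot.astype(np.float64) * 0.9 + 0.05
        probs += rng.uniform(0, 0.05, probs.shape)
        probs /= probs.sum(-1, keepdims=True)
        post = postprocess(probs).labels
        per_class = [dice(post == v, labels.labels == v)
                     for v in (0, 255, 125)]
        assert float(np.mean(per_class)) >= 0.95


class TestEvaluateCase:
    def test_identical_volumes_score_one(self):
        rng = np.random.default_rng(4)
        labels = rng.choice([0, 125, 255], size=(8, 8, 4)).astype(np.uint8)
        row = evaluate_case(labels, labels, case_id="x")
        for key in ("background_dice", "wall_dice", "tumor_dice",
                    "overall_dice"):
            assert row[key] == 1.0

    def test_all_background_prediction(self):
        truth = np.zeros((8, 8, 4), dtype=np.uint8)
        truth[2:5, 2:5, :] = 255
        truth[3, 3, 1] = 125
        pred = np.zeros_like(truth)
        row = evaluate_case(pred, truth)
        assert row["wall_dice"] == 0.0
        assert row["tumor_dice"] == 0.0
        assert row["overall_dice"] == pytest.approx(row["background_dice"] / 3)

    def test_report_schema_matches_results_table(self):
        report = DiceReport()
        row = evaluate_case(np.zeros((2, 2, 2), dtype=np.uint8),
                            np.zeros((2, 2, 2), dtype=np.uint8), case_id="c0")
        report.add(row, model="U-Net-5", na=10, train_size=7)
        df = report.summary()
        assert list(df.columns) == ["model", "na", "train_size",
                                    "overall_dice", "wall_dice", "tumor_dice",
                                    "background_dice"]

    def test_invalid_labels_rejected(self):
        with pytest.raises(Exception):
            evaluate_case(np.full((2, 2, 2), 7, dtype=np.uint8),
                          np.zeros((2, 2, 2), dtype=np.uint8))


class TestRunExperiment:
    def test_tiny_grid_trains_and_reports(self, cohort_dir, tmp_path):
        from bladderseg.posteval import run_experiment

        case_dirs = sorted(p for p in cohort_dir.iterdir() if p.is_dir())
        results, manifest = run_experiment(
            case_dirs, architectures=(4,), scenarios=(5,), train_sizes=(2,),
            n_test=1, seed=0,
            model_kwargs={"base_filters": 2, "input_shape": (32, 32, 8, 1)},
            train_kwargs={"max_epochs": 2},
            out_dir=tmp_path,
        )
        assert len(results) == 1  # one cell x one test case
        assert set(results.columns) >= {"model", "na", "train_size", "case_id",
                                        "wall_dice", "tumor_dice",
                                        "background_dice", "overall_dice"}
        assert results["overall_dice"].between(0, 1).all()
        assert sorted(manifest["role"].unique()) == ["test", "train_pool"]
        assert (tmp_path / "results.csv").exists()
        assert (tmp_path / "split.csv").exists()

    def test_insufficient_cases_rejected(self, cohort_dir):
        from bladderseg.posteval import run_experiment

        case_dirs = sorted(p for p in cohort_dir.iterdir() if p.is_dir())
        with pytest.raises(ValueError, match="at least"):
            run_experiment(case_dirs, architectures=(4,), scenarios=(5,),
                           train_sizes=(7,), n_test=5, seed=0)
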