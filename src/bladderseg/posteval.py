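"""Post-processing and evaluation.

Predicted per-voxel probability maps are smoothed slice-wise with an
edge-preserving bilateral filter (suppressing small spurious responses while
keeping large confident regions), then binarized by per-voxel argmax into
the {0, 255, 125} label convention. Agreement with ground truth is measured
per class with the Dice similarity coefficient

    Dice = 2 |A ∩ B| / (|A| + |B|)

and reported as wall, tumor and background Dice plus their unweighted mean
("overall"). ``run_experiment`` drives the model-family grid: architectures
x augmentation scenarios x training-set sizes, each trained from a fixed
seed and evaluated on held-out cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.restoration import denoise_bilateral

from .prep import CLASS_NAMES, LABEL_VALUES, LabelVolume, from_onehot

__all__ = ["DiceReport", "dice", "bilateral_filter_probs", "binarize",
           "evaluate_case", "run_experiment", "postprocess"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|) between two binary masks.

    Two empty masks agree perfectly (1.0); empty vs non-empty is 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a != 0
    b = b != 0
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / denom


def bilateral_filter_probs(probmap: np.ndarray, sigma_spatial: float = 1.5,
                           sigma_intensity: float = 0.3) -> np.ndarray:
    """Edge-preserving smoothing of a (rows, cols, slices, 3) probability map.

    Applied slice-wise (2D) to each class channel; channels are renormalized
    to sum to 1 per voxel afterwards. ``sigma_intensity`` is on the [0, 1]
    probability scale: large enough by default that isolated spikes are
    averaged away while extended high-probability plateaus keep their
    interior values.
    """
    if sigma_spatial <= 0 or sigma_intensity <= 0:
        raise ValueError("bilateral sigmas must be > 0")
    probmap = np.asarray(probmap, dtype=np.float64)
    if probmap.ndim != 4 or probmap.shape[-1] != 3:
        raise ValueError(f"expected (r, c, s, 3) probabilities, got {probmap.shape}")
    out = np.empty_like(probmap)
    win = 2 * int(np.ceil(2 * sigma_spatial)) + 1
    for s in range(probmap.shape[2]):
        for ch in range(3):
            out[:, :, s, ch] = denoise_bilateral(
                np.ascontiguousarray(probmap[:, :, s, ch]),
                sigma_color=sigma_intensity, sigma_spatial=sigma_spatial,
                win_size=win,
            )
    total = out.sum(axis=-1, keepdims=True)
    total[total == 0] = 1.0
    return out / total


def binarize(probmap: np.ndarray) -> LabelVolume:
    """Threshold a probability map into hard {0, 255, 125} labels.

    Per-voxel argmax over the three channels; exact ties resolve to the
    lower class index (background < wall < tumor).
    """
    probmap = np.asarray(probmap)
    if probmap.ndim != 4 or probmap.shape[-1] != 3:
        raise ValueError(f"expected (r, c, s, 3) probabilities, got {probmap.shape}")
    return LabelVolume(from_onehot(probmap))


def postprocess(probmap: np.ndarray, sigma_spatial: float = 1.5,
                sigma_intensity: float = 0.3) -> LabelVolume:
    """Bilateral filter then binarize — the full test-time post-processing."""
    return binarize(bilateral_filter_probs(probmap, sigma_spatial,
                                           sigma_intensity))


def evaluate_case(predicted: LabelVolume | np.ndarray,
                  truth: LabelVolume | np.ndarray,
                  case_id: str = "") -> dict:
    """One report row: per-class Dice plus their unweighted mean."""
    pred = predicted.labels if isinstance(predicted, LabelVolume) else np.asarray(predicted)
    true = truth.labels if isinstance(truth, LabelVolume) else np.asarray(truth)
    pred = LabelVolume(pred).labels  # validates the label convention
    true = LabelVolume(true).labels
    if pred.shape != true.shape:
        raise ValueError(f"shapes differ: {pred.shape} vs {true.shape}")
    row = {"case_id": case_id}
    for name, value in zip(CLASS_NAMES, LABEL_VALUES):
        row[f"{name}_dice"] = dice(pred == value, true == value)
    row["overall_dice"] = float(
        np.mean([row[f"{n}_dice"] for n in CLASS_NAMES])
    )
    return row


@dataclass
class DiceReport:
    """Per-case rows plus aggregate means per experiment cell."""

    rows: list[dict] = field(default_factory=list)

    def add(self, row: dict, **cell) -> None:
        self.rows.append({**cell, **row})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self, by=("model", "na", "train_size")) -> pd.DataFrame:
        """Aggregate table in the results-table layout (one row per cell)."""
        df = self.to_dataframe()
        keys = [k for k in by if k in df.columns]
        cols = ["overall_dice", "wall_dice", "tumor_dice", "background_dice"]
        return df.groupby(keys, as_index=False)[cols].mean()


def run_experiment(case_dirs, architectures=(4, 5, 6), scenarios=(5, 10),
                   train_sizes=(7,), n_test: int = 5, seed: int = 0,
                   model_kwargs: dict | None = None,
                   train_kwargs: dict | None = None,
                   out_dir=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train and evaluate every (architecture, na, train_size) grid cell.

    Cases are split once: the last ``n_test`` (after a seeded shuffle) are
    held out for testing, the first ``max(train_sizes)`` feed training.
    Returns (per-case results, split manifest); both are written as CSV when
    ``out_dir`` is given. Model and trainer defaults can be overridden for
    desk-scale runs via ``model_kwargs``/``train_kwargs``.
    """
    from .augment import AugmentationScenario, build_training_set
    from .prep import preprocess_case
    from .trainer import TrainConfig, train
    from .unet3d import ModelSpec, build_model
    from .volio import load_case

    case_dirs = [Path(d) for d in case_dirs]
    need = max(train_sizes) + n_test
    if len(case_dirs) < need:
        raise ValueError(
            f"need at least {need} cases (max train size {max(train_sizes)} "
            f"+ {n_test} test), got {len(case_dirs)}"
        )
    model_kwargs = dict(model_kwargs or {})
    train_kwargs = dict(train_kwargs or {})
    target = model_kwargs.get("input_shape", (128, 128, 32, 1))[:3]

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_dirs))
    test_idx = order[-n_test:]
    split_rows = [{"case_id": case_dirs[i].name,
                   "role": "test" if i in set(test_idx) else "train_pool"}
                  for i in order]
    manifest = pd.DataFrame(split_rows)

    preprocessed = {}
    for i in order:
        volume, masks = load_case(case_dirs[i])
        img, labels = preprocess_case(volume, masks, target=target)
        preprocessed[i] = (img, labels)

    report = DiceReport()
    for train_size in train_sizes:
        pool = [i for i in order if i not in set(test_idx)][:train_size]
        for blocks in architectures:
            for na in scenarios:
                scenario = AugmentationScenario.for_na(na, seed=seed)
                cases = [(preprocessed[i][0], preprocessed[i][1].labels)
                         for i in pool]
                train_pairs, val_pairs = build_training_set(cases, scenario)
                train_set = [(img, LabelVolume(lab).onehot)
                             for img, lab in train_pairs]
                val_set = [(img, LabelVolume(lab).onehot)
                           for img, lab in val_pairs]
                spec = ModelSpec(num_blocks=blocks, seed=seed, **model_kwargs)
                model = build_model(spec)
                config = TrainConfig(seed=seed, **train_kwargs)
                train(model, train_set, val_set, config)
                for i in test_idx:
                    img, labels = preprocessed[i]
                    probs = model.predict(img[..., None])[0]
                    pred = postprocess(probs)
                    row = evaluate_case(pred, labels,
                                        case_id=case_dirs[i].name)
                    report.add(row, model=f"U-Net-{blocks}", na=na,
                               train_size=train_size)
                    if out_dir is not None:
                        from .volio import write_nrrd

                        pred_dir = (Path(out_dir) / "predictions" /
                                    f"unet{blocks}_na{na}_train{train_size}")
                        write_nrrd(pred_dir / f"{case_dirs[i].name}.nrrd",
                                   pred.labels)
    results = report.to_dataframe()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "results.csv", index=False)
        report.summary().to_csv(out_dir / "summary.csv", index=False)
        manifest.to_csv(out_dir / "split.csv", index=False)
    return results, manifest
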