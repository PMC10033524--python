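"""Data multiplication: in-plane rotations, horizontal flips, elastic warps.

Every transform is applied with identical geometry to the intensity volume
and its label grid — trilinear resampling for intensities, nearest-neighbour
for labels, so the {0, 255, 125} label set is preserved. Two scenarios are
shipped, na=5 and na=10 augmented volumes per original; each original
additionally contributes one independently drawn augmentation to the
validation set.

Scenario compositions (configurable):

* na=10 — 3 positive rotations (angle ~ U[5, 10] deg), 3 negative rotations
  (U[-10, -5] deg), with a fixed subset of the six flipped horizontally,
  plus 4 elastic warps (2 random fields x {original, flipped}).
* na=5 — 2 positive + 1 negative rotation with one of them flipped, plus
  2 elastic warps on the original.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, rotate as _nd_rotate

__all__ = ["AugmentationScenario", "ScenarioError", "rotate_case",
           "elastic_case", "augment_case", "build_training_set"]


class ScenarioError(ValueError):
    """Inconsistent augmentation scenario configuration."""


@dataclass(frozen=True)
class AugmentationScenario:
    """The na parameter plus the composition realizing it."""

    na: int
    pos_angle_range: tuple[float, float] = (5.0, 10.0)  # degrees
    neg_angle_range: tuple[float, float] = (-10.0, -5.0)
    n_pos_rot: int = 3
    n_neg_rot: int = 3
    n_elastic: int = 4
    # one flag per rotated copy (positives first), True = flip after rotation
    flip_assignment: tuple[bool, ...] = (False, True, False, True, True, False)
    elastic_alpha: float = 2.0  # peak displacement, voxels
    elastic_sigma: float = 32.0  # field smoothness, voxels
    elastic_on_flipped: bool = True  # reuse each field on the flipped volume
    seed: int = 0

    def __post_init__(self):
        if self.n_pos_rot + self.n_neg_rot + self.n_elastic != self.na:
            raise ScenarioError(
                f"composition {self.n_pos_rot}+{self.n_neg_rot}+"
                f"{self.n_elastic} != na={self.na}"
            )
        if len(self.flip_assignment) != self.n_pos_rot + self.n_neg_rot:
            raise ScenarioError(
                "flip_assignment must have one flag per rotated copy"
            )

    @classmethod
    def for_na(cls, na: int, seed: int = 0, **overrides) -> "AugmentationScenario":
        """The shipped composition for na=5 or na=10."""
        if na == 10:
            base = dict(na=10, n_pos_rot=3, n_neg_rot=3, n_elastic=4,
                        flip_assignment=(False, True, False, True, True, False),
                        elastic_on_flipped=True)
        elif na == 5:
            base = dict(na=5, n_pos_rot=2, n_neg_rot=1, n_elastic=2,
                        flip_assignment=(False, True, False),
                        elastic_on_flipped=False)
        else:
            raise ScenarioError(f"no shipped composition for na={na}")
        base.update(overrides, seed=seed)
        return cls(**base)


def _flip(arr: np.ndarray) -> np.ndarray:
    return arr[:, ::-1]  # mirror along the column (left-right) axis


def rotate_case(image: np.ndarray, labels: np.ndarray, angle_deg: float,
                flip: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """In-plane rotation about the slice axis, optional horizontal flip after."""
    if angle_deg == 0.0:
        img, lab = image, labels
    else:
        img = _nd_rotate(image, angle_deg, axes=(0, 1), reshape=False,
                         order=1, mode="constant", cval=0.0)
        lab = _nd_rotate(labels, angle_deg, axes=(0, 1), reshape=False,
                         order=0, mode="constant", cval=0)
    if flip:
        img, lab = _flip(img), _flip(lab)
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def _displacement_field(shape, rng: np.random.Generator, alpha: float,
                        sigma: float) -> list[np.ndarray]:
    """Smooth random in-plane displacement (rows, cols); slices undisplaced."""
    field = []
    for _ in range(2):
        d = gaussian_filter(rng.uniform(-1.0, 1.0, size=shape), sigma,
                            mode="constant")
        m = np.abs(d).max()
        field.append((d / m * alpha) if m > 0 else d)
    field.append(np.zeros(shape))
    return field


def elastic_case(image: np.ndarray, labels: np.ndarray,
                 rng: np.random.Generator, alpha: float = 2.0,
                 sigma: float = 32.0, flip: bool = False
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Warp image and labels with one shared smooth displacement field.

    The field is Gaussian-filtered uniform noise rescaled so the largest
    displacement equals ``alpha`` voxels; smoothness grows with ``sigma``.
    ``alpha = 0`` is the exact identity.
    """
    if alpha < 0 or sigma <= 0:
        raise ValueError("elastic parameters must be positive (alpha may be 0)")
    if flip:
        image, labels = _flip(image), _flip(labels)
    if alpha == 0.0:
        return np.ascontiguousarray(image), np.ascontiguousarray(labels)
    disp = _displacement_field(image.shape, rng, alpha, sigma)
    coords = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in image.shape),
                         indexing="ij")
    coords = [c + d for c, d in zip(coords, disp)]
    img = map_coordinates(image, coords, order=1, mode="nearest")
    lab = map_coordinates(labels, coords, order=0, mode="nearest")
    return img.astype(image.dtype, copy=False), lab.astype(labels.dtype, copy=False)


def augment_case(image: np.ndarray, labels: np.ndarray,
                 scenario: AugmentationScenario,
                 rng: np.random.Generator | None = None
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Produce exactly ``scenario.na`` transformed (image, labels) pairs.

    Rotation angles are drawn fresh from the scenario's ranges; elastic
    fields are drawn fresh per call. Pass a shared ``rng`` to chain several
    cases deterministically; otherwise one is seeded from the scenario.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    out = []
    angles = [rng.uniform(*scenario.pos_angle_range)
              for _ in range(scenario.n_pos_rot)]
    angles += [rng.uniform(*scenario.neg_angle_range)
               for _ in range(scenario.n_neg_rot)]
    for angle, flip in zip(angles, scenario.flip_assignment):
        out.append(rotate_case(image, labels, angle, flip=flip))
    if scenario.elastic_on_flipped:
        n_fields, variants = scenario.n_elastic // 2, (False, True)
    else:
        n_fields, variants = scenario.n_elastic, (False,)
    for _ in range(n_fields):
        field_seed = int(rng.integers(0, 2**31 - 1))
        for flip in variants:
            out.append(elastic_case(image, labels,
                                    np.random.default_rng(field_seed),
                                    alpha=scenario.elastic_alpha,
                                    sigma=scenario.elastic_sigma, flip=flip))
    assert len(out) == scenario.na
    return out


def build_training_set(cases, scenario: AugmentationScenario
                       ) -> tuple[list, list]:
    """Expand preprocessed cases into training and validation sets.

    ``cases`` is a sequence of (image, labels) pairs. The training set holds
    every original plus its na augmentations (x originals -> x*(1+na)
    volumes); the validation set holds one additional, independently drawn
    rotation per original. Fully determined by (cases, scenario.seed).
    """
    cases = list(cases)
    if not cases:
        raise ValueError("need at least one case")
    rng = np.random.default_rng(scenario.seed)
    train, val = [], []
    for image, labels in cases:
        train.append((image, labels))
        train.extend(augment_case(image, labels, scenario, rng=rng))
        lo, hi = scenario.pos_angle_range
        angle = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
        val.append(rotate_case(image, labels, angle, flip=rng.random() < 0.5))
    return train, val
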