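"""Preprocessing: fixed ROI crop, resize, normalization, label encoding.

The model input contract is a 128x128x32 volume with zero mean and unit
standard deviation, paired with a label grid using the {0 background,
255 wall, 125 tumor} convention and its one-hot 3-channel form (channel
order: background, wall, tumor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .volio import CaseAlignmentError, MaskPair, MriVolume

__all__ = [
    "BACKGROUND", "WALL", "TUMOR", "LABEL_VALUES", "CLASS_NAMES",
    "RoiSizeError", "LabelEncodingError", "LabelVolume",
    "extract_roi", "resize_volume", "normalize", "encode_masks",
    "to_onehot", "from_onehot", "preprocess_case",
]

BACKGROUND, WALL, TUMOR = 0, 255, 125
LABEL_VALUES = (BACKGROUND, WALL, TUMOR)  # indexed by class channel
CLASS_NAMES = ("background", "wall", "tumor")

ROI_LO, ROI_HI = 100, 400  # in-plane crop window, 0-based half-open
ROI_DEPTH = 32
TARGET_SHAPE = (128, 128, 32)


class RoiSizeError(ValueError):
    """In-plane grid too small for the fixed ROI window."""


class LabelEncodingError(ValueError):
    """A label grid contains values outside {0, 255, 125}."""


@dataclass
class LabelVolume:
    """Integer label grid in the {0, 255, 125} convention."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        bad = np.setdiff1d(np.unique(self.labels), LABEL_VALUES)
        if bad.size:
            raise LabelEncodingError(
                f"labels outside {{0, 255, 125}}: {bad[:10].tolist()}"
            )

    @property
    def shape(self):
        return self.labels.shape

    @property
    def onehot(self) -> np.ndarray:
        return to_onehot(self.labels)

    def class_mask(self, channel: int) -> np.ndarray:
        return (self.labels == LABEL_VALUES[channel]).astype(np.uint8)


def extract_roi(volume: np.ndarray, depth: int = ROI_DEPTH) -> np.ndarray:
    """Crop the fixed in-plane window rows/cols [100, 400) and 32 slices.

    The slice axis is center-cropped when deeper than ``depth`` and
    zero-padded symmetrically when shallower. Requires an in-plane grid of
    at least 400x400; smaller inputs must be resized or padded upstream,
    since the fixed window is undefined for them.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected 3D volume, got shape {volume.shape}")
    rows, cols, slices = volume.shape
    if rows < ROI_HI or cols < ROI_HI:
        raise RoiSizeError(
            f"in-plane size {rows}x{cols} < {ROI_HI}x{ROI_HI}: resize or pad "
            f"the volume upstream before ROI extraction"
        )
    out = volume[ROI_LO:ROI_HI, ROI_LO:ROI_HI, :]
    if slices > depth:
        start = (slices - depth) // 2
        out = out[:, :, start:start + depth]
    elif slices < depth:
        lo = (depth - slices) // 2
        out = np.pad(out, ((0, 0), (0, 0), (lo, depth - slices - lo)))
    return out


def resize_volume(volume: np.ndarray, target=TARGET_SHAPE,
                  is_mask: bool = False) -> np.ndarray:
    """Resize to ``target``: trilinear for intensities, nearest for labels.

    Nearest-neighbour resampling preserves the label set exactly.
    """
    volume = np.asarray(volume)
    target = tuple(int(t) for t in target)
    if len(target) != volume.ndim or any(t < 1 for t in target):
        raise ValueError(f"bad target shape {target} for input {volume.shape}")
    order = 0 if is_mask else 1
    out = _sk_resize(volume, target, order=order, preserve_range=True,
                     anti_aliasing=False)
    return out.astype(volume.dtype if is_mask else np.float32)


def normalize(volume: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Shift/scale to mean 0, standard deviation 1 (over all voxels).

    A constant volume maps to all zeros (the degenerate sigma is guarded).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.size <= 1:
        raise ValueError("normalization needs more than one voxel")
    sd = volume.std()
    if sd < eps:
        return np.zeros_like(volume, dtype=np.float32)
    return ((volume - volume.mean()) / sd).astype(np.float32)


def encode_masks(masks: MaskPair) -> LabelVolume:
    """Merge the binary wall/tumor masks into one {0, 255, 125} label grid.

    Tumor takes precedence where the masks overlap.
    """
    if masks.wall.shape != masks.tumor.shape:
        raise CaseAlignmentError(
            f"wall {masks.wall.shape} vs tumor {masks.tumor.shape}"
        )
    labels = np.zeros(masks.wall.shape, dtype=np.uint8)
    labels[masks.wall != 0] = WALL
    labels[masks.tumor != 0] = TUMOR
    return LabelVolume(labels)


def to_onehot(labels: np.ndarray) -> np.ndarray:
    """Labels {0, 255, 125} -> binary channels (background, wall, tumor).

    Channels sum to exactly 1 at every voxel.
    """
    labels = np.asarray(labels)
    bad = np.setdiff1d(np.unique(labels), LABEL_VALUES)
    if bad.size:
        raise LabelEncodingError(
            f"labels outside {{0, 255, 125}}: {bad[:10].tolist()}"
        )
    onehot = np.stack([(labels == v) for v in LABEL_VALUES], axis=-1)
    return onehot.astype(np.float32)


def from_onehot(channels: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`to_onehot`."""
    channels = np.asarray(channels)
    if channels.shape[-1] != 3:
        raise ValueError(f"expected 3 channels, got shape {channels.shape}")
    idx = channels.argmax(axis=-1)
    lut = np.array(LABEL_VALUES, dtype=np.uint8)
    return lut[idx]


def preprocess_case(volume: MriVolume, masks: MaskPair,
                    target=TARGET_SHAPE) -> tuple[np.ndarray, LabelVolume]:
    """Full per-case preprocessing to the model input contract.

    Image: ROI crop -> resize -> normalize. Masks: ROI crop -> nearest resize
    -> {0, 255, 125} encoding. Returns the float32 image and its LabelVolume,
    both of shape ``target``.
    """
    img = normalize(resize_volume(extract_roi(volume.voxels), target))
    wall = resize_volume(extract_roi(masks.wall), target, is_mask=True)
    tumor = resize_volume(extract_roi(masks.tumor), target, is_mask=True)
    labels = encode_masks(MaskPair(wall, tumor, case_id=masks.case_id))
    return img, labels
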