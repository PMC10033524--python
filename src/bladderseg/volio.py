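"""Per-case NRRD I/O.

A case on disk is a directory with three NRRD files: the T2 intensity volume
(``image.nrrd``) and two binary masks (``wall.nrrd``, ``tumor.nrrd``) drawn
by radiologists. Arrays are handled in ``(rows, cols, slices)`` index order,
0-based, with the slice axis being the acquisition (axial) axis; SimpleITK's
native z-y-x order is transposed on the way in and out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

__all__ = [
    "MriVolume",
    "MaskPair",
    "NrrdFormatError",
    "DimensionalityError",
    "CaseAlignmentError",
    "MissingComponentError",
    "read_nrrd",
    "write_nrrd",
    "load_case",
    "CASE_FILES",
]

CASE_FILES = ("image.nrrd", "wall.nrrd", "tumor.nrrd")

_SPACING_FIELDS = ("spacings", "space directions")


class NrrdFormatError(ValueError):
    """The file is not a readable NRRD."""


class DimensionalityError(ValueError):
    """The NRRD payload is not a 3D scalar volume."""


class CaseAlignmentError(ValueError):
    """Image and mask grids of one case do not share a shape."""


class MissingComponentError(FileNotFoundError):
    """A case directory lacks one of its three required files."""


@dataclass
class MriVolume:
    """A 3D scalar intensity grid with voxel spacing and a case identifier."""

    voxels: np.ndarray  # (rows, cols, slices)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm per voxel
    case_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise DimensionalityError(
                f"MriVolume needs a 3D grid, got shape {self.voxels.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class MaskPair:
    """Aligned binary wall and tumor masks for one case."""

    wall: np.ndarray
    tumor: np.ndarray
    case_id: str = ""

    def __post_init__(self):
        self.wall = np.asarray(self.wall)
        self.tumor = np.asarray(self.tumor)
        if self.wall.shape != self.tumor.shape:
            raise CaseAlignmentError(
                f"wall {self.wall.shape} vs tumor {self.tumor.shape}"
            )
        for name, m in (("wall", self.wall), ("tumor", self.tumor)):
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{name} mask is not binary: values {vals[:10]}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.wall.shape


def _header_has_spacing(path: Path) -> bool:
    # The NRRD header is plain text up to the first blank line, even when the
    # data payload is gzip-encoded; a detached .nhdr is all text.
    try:
        head = path.read_bytes()[:4096]
    except OSError:
        return False
    header = head.split(b"\n\n", 1)[0].decode("latin-1", errors="replace").lower()
    return any(f + ":" in header for f in _SPACING_FIELDS)


def read_nrrd(path) -> tuple[np.ndarray, dict]:
    """Read one NRRD volume as a ``(rows, cols, slices)`` array plus metadata.

    Returns the voxel grid re-ordered from the file's z-y-x storage to
    (rows, cols, slices). Spacing comes from the header when present,
    otherwise defaults to (1, 1, 1) with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise MissingComponentError(str(path))
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise NrrdFormatError(f"{path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D volume, got {img.GetDimension()}D"
        )
    arr = sitk.GetArrayFromImage(img)  # (slices, rows, cols)
    arr = np.transpose(arr, (1, 2, 0))  # -> (rows, cols, slices)
    sx, sy, sz = img.GetSpacing()  # (col, row, slice) in sitk's x-y-z
    spacing = (float(sy), float(sx), float(sz))
    if not _header_has_spacing(path):
        spacing = (1.0, 1.0, 1.0)
        logger.warning("%s: header carries no spacing; assuming (1, 1, 1)", path)
    meta = {"spacing": spacing, "path": str(path)}
    return arr, meta


def write_nrrd(path, array: np.ndarray,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a ``(rows, cols, slices)`` array as NRRD with the given spacing."""
    array = np.asarray(array)
    if array.ndim != 3:
        raise DimensionalityError(f"expected 3D array, got shape {array.shape}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(array, (2, 0, 1))))
    sr, sc, ss = spacing
    img.SetSpacing((float(sc), float(sr), float(ss)))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def load_case(case_dir, names: tuple[str, str, str] = CASE_FILES
              ) -> tuple[MriVolume, MaskPair]:
    """Load one case directory into an (MriVolume, MaskPair) record.

    Masks are coerced to {0, 1} (any nonzero voxel becomes 1); the three
    grids must share a shape.
    """
    case_dir = Path(case_dir)
    paths = [case_dir / n for n in names]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise MissingComponentError(
            f"case {case_dir} is missing: {', '.join(missing)}"
        )
    image, meta = read_nrrd(paths[0])
    wall, _ = read_nrrd(paths[1])
    tumor, _ = read_nrrd(paths[2])
    shapes = [image.shape, wall.shape, tumor.shape]
    if len({tuple(s) for s in shapes}) != 1:
        raise CaseAlignmentError(
            f"case {case_dir}: image {shapes[0]}, wall {shapes[1]}, "
            f"tumor {shapes[2]}"
        )
    case_id = case_dir.name
    volume = MriVolume(image, spacing=meta["spacing"], case_id=case_id)
    masks = MaskPair((wall != 0).astype(np.uint8), (tumor != 0).astype(np.uint8),
                     case_id=case_id)
    return volume, masks
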