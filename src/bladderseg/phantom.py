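"""Synthetic bladder phantoms.

Stands in for the private clinical cohort: each case is a T2-like intensity
volume plus aligned binary wall and tumor masks. The geometry mimics a
distended bladder on axial T2 — a bright (fluid) ellipsoidal lumen, a darker
closed wall shell a few voxels thick, and an intermediate-intensity tumor
blob attached to the inner wall — positioned so the pipeline's fixed
in-plane ROI window (rows/cols 100..399) captures the whole organ.
Intensities follow the T2 ordering (lumen > tumor > wall > background);
noise is additive Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .volio import MaskPair, MriVolume, write_nrrd

__all__ = ["PhantomConfig", "DetachedTumorError", "generate_phantom",
           "generate_cohort"]

# in-plane window the fixed ROI crop extracts; the whole outer ellipsoid
# must land inside it
_ROI_LO, _ROI_HI = 100, 400


class DetachedTumorError(ValueError):
    """The configured tumor does not touch the wall shell."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast and noise of one synthetic case."""

    grid_shape: tuple[int, int, int] = (512, 512, 32)
    bladder_center: tuple[float, float, float] = (250.0, 250.0, 16.0)
    bladder_radii: tuple[float, float, float] = (80.0, 100.0, 12.0)
    wall_thickness: float = 4.0  # voxels
    tumor_radius: float = 12.0  # voxels
    tumor_angle: float = 0.7  # radians, position on the inner wall
    tumor_center: tuple[float, float, float] | None = None  # overrides angle
    intensity_lumen: float = 200.0
    intensity_wall: float = 60.0
    intensity_tumor: float = 120.0
    intensity_background: float = 30.0
    noise_sd: float = 10.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)  # mm
    seed: int = 0

    def validate(self) -> None:
        if self.wall_thickness < 1:
            raise ValueError(f"wall_thickness must be >= 1, got {self.wall_thickness}")
        if self.tumor_radius < 1:
            raise ValueError(f"tumor_radius must be >= 1, got {self.tumor_radius}")
        if min(self.bladder_radii) <= self.wall_thickness:
            raise ValueError("bladder_radii must exceed wall_thickness on every axis")
        for axis in range(3):
            c, r, n = (self.bladder_center[axis], self.bladder_radii[axis],
                       self.grid_shape[axis])
            if c - r < 0 or c + r >= n:
                raise ValueError(
                    f"axis {axis}: ellipsoid (center {c}, radius {r}) leaves "
                    f"the {n}-voxel grid"
                )
        for axis in range(2):  # in-plane ROI containment
            c, r = self.bladder_center[axis], self.bladder_radii[axis]
            if c - r < _ROI_LO or c + r >= _ROI_HI:
                raise ValueError(
                    f"axis {axis}: outer ellipsoid must sit inside the "
                    f"[{_ROI_LO}, {_ROI_HI}) ROI window"
                )


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float32)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def generate_phantom(config: PhantomConfig) -> tuple[MriVolume, MaskPair]:
    """Render one phantom case from its configuration.

    Pure function of (config, seed): the wall mask is the closed ellipsoidal
    shell (outer minus inner ellipsoid), the tumor a sphere centered on the
    inner wall surface and clipped to the organ, with tumor taking precedence
    over wall where they overlap. Raises :class:`DetachedTumorError` when the
    tumor sphere misses the shell entirely (the pipeline's premise is a
    wall-attached lesion).
    """
    config.validate()
    shape = config.grid_shape
    center = config.bladder_center
    outer = _ellipsoid(shape, center, config.bladder_radii)
    inner_radii = tuple(r - config.wall_thickness for r in config.bladder_radii)
    inner = _ellipsoid(shape, center, inner_radii)
    shell = outer & ~inner

    tumor_center = config.tumor_center or (
        center[0] + inner_radii[0] * math.cos(config.tumor_angle),
        center[1] + inner_radii[1] * math.sin(config.tumor_angle),
        center[2],
    )
    sphere = _ellipsoid(shape, tumor_center, (config.tumor_radius,) * 3)
    tumor = sphere & outer  # clipped to lumen ∪ wall
    if not (sphere & shell).any():
        raise DetachedTumorError(
            "tumor sphere does not intersect the wall shell; move it onto "
            "the inner wall surface or enlarge it"
        )
    wall = shell & ~tumor  # masks stay disjoint
    lumen = inner & ~tumor

    intensity = np.full(shape, config.intensity_background, dtype=np.float32)
    intensity[lumen] = config.intensity_lumen
    intensity[wall] = config.intensity_wall
    intensity[tumor] = config.intensity_tumor
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        intensity = intensity + rng.normal(
            0.0, config.noise_sd, size=shape
        ).astype(np.float32)

    case_id = f"phantom_{config.seed:04d}"
    volume = MriVolume(intensity, spacing=config.spacing, case_id=case_id)
    masks = MaskPair(wall.astype(np.uint8), tumor.astype(np.uint8),
                     case_id=case_id)
    return volume, masks


def _jitter(template: PhantomConfig, rng: np.random.Generator,
            seed: int, jitter_frac: float = 0.2) -> PhantomConfig:
    radii = tuple(r * rng.uniform(1 - jitter_frac, 1 + jitter_frac)
                  for r in template.bladder_radii)
    center = (
        template.bladder_center[0] + rng.uniform(-10, 10),
        template.bladder_center[1] + rng.uniform(-10, 10),
        template.bladder_center[2],
    )
    return replace(
        template,
        bladder_center=center,
        bladder_radii=radii,
        tumor_radius=template.tumor_radius * rng.uniform(1 - jitter_frac,
                                                         1 + jitter_frac),
        tumor_angle=rng.uniform(0.0, 2.0 * math.pi),
        seed=seed,
    )


def generate_cohort(n_cases: int, config_template: PhantomConfig | None = None,
                    seed: int = 0, out_dir=None,
                    jitter_frac: float = 0.2) -> list[Path]:
    """Write ``n_cases`` jittered phantom cases as NRRD case directories.

    Each case directory gets image/wall/tumor NRRD files plus a shared
    ``manifest.csv`` (one row per case with the generation parameters).
    Geometry is jittered uniformly within ±``jitter_frac`` of the template
    radii; the tumor position is re-drawn per case. Deterministic in
    (template, seed).
    """
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    if out_dir is None:
        raise ValueError("out_dir is required")
    template = config_template or PhantomConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    case_dirs: list[Path] = []
    rows = []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        cfg = _jitter(template, rng, case_seed, jitter_frac)
        volume, masks = generate_phantom(cfg)
        case_dir = out_dir / f"case_{i:03d}"
        write_nrrd(case_dir / "image.nrrd", volume.voxels, cfg.spacing)
        write_nrrd(case_dir / "wall.nrrd", masks.wall, cfg.spacing)
        write_nrrd(case_dir / "tumor.nrrd", masks.tumor, cfg.spacing)
        case_dirs.append(case_dir)
        rows.append({
            "case_id": case_dir.name,
            "seed": case_seed,
            "radius_row": cfg.bladder_radii[0],
            "radius_col": cfg.bladder_radii[1],
            "radius_slice": cfg.bladder_radii[2],
            "center_row": cfg.bladder_center[0],
            "center_col": cfg.bladder_center[1],
            "center_slice": cfg.bladder_center[2],
            "wall_thickness": cfg.wall_thickness,
            "tumor_radius": cfg.tumor_radius,
            "tumor_angle": cfg.tumor_angle,
            "noise_sd": cfg.noise_sd,
        })
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return case_dirs
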