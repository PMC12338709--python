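"""MRS voxel geometry and tissue-fraction extraction.

The MRS voxel is a cm-scale acquisition box (here typically 3x3x3 cm^3)
placed inside a mm-scale anatomical image grid.  This module builds a
partial-volume weight mask for the (possibly oblique) box on the image
grid and averages gray-matter / white-matter / CSF probability maps
inside it to obtain the normalized tissue fractions f_GM, f_WM, f_CSF
that drive the water-referenced concentration correction.

Conventions: world coordinates in mm (RAS), 0-based voxel indices, the
affine taken verbatim from the NIfTI header.  Probability maps are never
resampled; the mask is computed on their native grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "SegmentationMaps",
    "VoxelGeometry",
    "TissueFractions",
    "load_probability_maps",
    "build_voxel_mask",
    "extract_fractions",
    "normalize_fractions",
]

#: Values outside [0,1] by more than this are an error; smaller
#: excursions (interpolation ringing) are clamped silently.
_PROB_TOL = 1e-3

#: Below this pre-normalization sum the voxel is mostly non-brain and
#: renormalizing would rescale noise; fail loudly instead.
_DEGENERATE_SUM = 0.5


@dataclass(frozen=True)
class SegmentationMaps:
    """Co-registered GM/WM/CSF probability volumes on one grid."""

    prob_gm: np.ndarray
    prob_wm: np.ndarray
    prob_csf: np.ndarray
    affine: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.prob_gm.shape

    def __post_init__(self) -> None:
        for name in ("prob_gm", "prob_wm", "prob_csf"):
            vol = getattr(self, name)
            if vol.ndim != 3:
                raise ValueError(f"{name} must be 3-D, got {vol.ndim}-D")
            if vol.shape != self.prob_gm.shape:
                raise ValueError("grid mismatch: probability maps differ in shape")
            if vol.min() < -1e-12 or vol.max() > 1 + 1e-12:
                raise ValueError(f"{name} contains probabilities outside [0,1]")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")


@dataclass(frozen=True)
class VoxelGeometry:
    """MRS acquisition box: center (mm), edge lengths (mm), orientation.

    ``orientation`` rows are the unit vectors along the three box edges
    in world space; identity means an axis-aligned box.
    """

    center_mm: np.ndarray
    edge_mm: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center_mm", np.asarray(self.center_mm, float))
        object.__setattr__(self, "edge_mm", np.asarray(self.edge_mm, float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, float))
        if self.center_mm.shape != (3,) or self.edge_mm.shape != (3,):
            raise ValueError("center_mm and edge_mm must be length-3")
        if np.any(self.edge_mm <= 0):
            raise ValueError("edge lengths must be positive")
        R = self.orientation
        if R.shape != (3, 3) or np.linalg.norm(R.T @ R - np.eye(3)) >= 1e-8:
            raise ValueError("orientation must be an orthonormal 3x3 matrix")

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGeometry":
        """Build from a config mapping (orientation row-major, optional)."""
        orientation = np.asarray(d.get("orientation", np.eye(3)), float).reshape(3, 3)
        return cls(
            center_mm=np.asarray(d["center_mm"], float),
            edge_mm=np.asarray(d["edge_mm"], float),
            orientation=orientation,
        )


@dataclass(frozen=True)
class TissueFractions:
    """Normalized GM/WM/CSF fractional volumes within one MRS voxel.

    Values produced by :func:`normalize_fractions` / :func:`extract_fractions`
    sum to 1 exactly; the constructor additionally tolerates the small
    sum deviations of fractions quoted to two decimals (e.g. published
    marginal means), which are used as-is rather than rescaled.
    """

    f_gm: float
    f_wm: float
    f_csf: float

    def __post_init__(self) -> None:
        for v in (self.f_gm, self.f_wm, self.f_csf):
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"fraction {v} outside [0,1]")
        if abs(self.f_gm + self.f_wm + self.f_csf - 1.0) > 0.015:
            raise ValueError("fractions must sum to 1 (within rounding)")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_gm, self.f_wm, self.f_csf])


def load_probability_maps(
    gm_path: str | Path, wm_path: str | Path, csf_path: str | Path
) -> SegmentationMaps:
    """Load three NIfTI probability maps sharing one grid and affine.

    Probabilities outside [0,1] by more than 1e-3 raise; smaller
    excursions are clamped.
    """
    imgs = [nib.load(str(p)) for p in (gm_path, wm_path, csf_path)]
    shapes = [img.shape for img in imgs]
    if any(len(s) != 3 for s in shapes):
        raise ValueError(f"probability maps must be 3-D, got shapes {shapes}")
    if len(set(shapes)) != 1:
        raise ValueError(f"grid mismatch: shapes {shapes}")
    affines = [img.affine for img in imgs]
    if not all(np.allclose(a, affines[0], atol=1e-6) for a in affines[1:]):
        raise ValueError("grid mismatch: affines differ between maps")
    vols = []
    for img, path in zip(imgs, (gm_path, wm_path, csf_path)):
        data = np.asarray(img.get_fdata(), float)
        if data.min() < -_PROB_TOL or data.max() > 1 + _PROB_TOL:
            raise ValueError(
                f"{path}: probabilities outside [0,1] beyond tolerance "
                f"(range [{data.min():.4g}, {data.max():.4g}])"
            )
        vols.append(np.clip(data, 0.0, 1.0))
    return SegmentationMaps(vols[0], vols[1], vols[2], np.asarray(affines[0], float))


def build_voxel_mask(
    maps: SegmentationMaps, geom: VoxelGeometry, supersample: int = 3
) -> np.ndarray:
    """Partial-volume weight of the MRS box on the image grid.

    Each image voxel receives a weight in [0,1] equal to the fraction of
    its volume inside the (possibly oblique) MRS box, estimated from
    ``supersample**3`` regularly spaced sample points per voxel.
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    A = maps.affine
    A3, t = A[:3, :3], A[:3, 3]
    inv_A = np.linalg.inv(A)

    # Bounding box of the MRS box in index space, padded by one voxel.
    half = geom.edge_mm / 2.0
    signs = np.array(np.meshgrid([-1, 1], [-1, 1], [-1, 1])).reshape(3, -1).T
    corners_world = geom.center_mm + (signs * half) @ geom.orientation
    corners_idx = (inv_A[:3, :3] @ corners_world.T).T + inv_A[:3, 3]
    lo = np.maximum(np.floor(corners_idx.min(axis=0)).astype(int) - 1, 0)
    hi = np.minimum(
        np.ceil(corners_idx.max(axis=0)).astype(int) + 1, np.array(maps.shape) - 1
    )
    weights = np.zeros(maps.shape, float)
    if np.any(hi < lo):
        raise ValueError("voxel outside image: MRS box does not intersect the FOV")

    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[d], hi[d] + 1) for d in range(3)), indexing="ij"
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)

    offsets_1d = (np.arange(supersample) + 0.5) / supersample - 0.5
    counts = np.zeros(len(idx), dtype=np.int64)
    # Loop over subsample offsets (supersample^3 passes) to bound memory.
    for ox in offsets_1d:
        for oy in offsets_1d:
            for oz in offsets_1d:
                pts = idx + (ox, oy, oz)
                world = pts @ A3.T + t
                local = (world - geom.center_mm) @ geom.orientation.T
                inside = np.all(np.abs(local) <= half, axis=1)
                counts += inside
    w = counts / float(supersample**3)
    weights[
        ii.reshape(-1), jj.reshape(-1), kk.reshape(-1)
    ] = w
    if weights.sum() == 0:
        raise ValueError("voxel outside image: MRS box does not intersect the FOV")
    return weights


def extract_fractions(maps: SegmentationMaps, mask: np.ndarray) -> TissueFractions:
    """Weighted mean tissue probabilities within the mask, normalized.

    f_x = sum(w * p_x) / sum(w * (p_gm + p_wm + p_csf)); the division is
    the sum-to-one normalization applied when the raw maps do not
    already sum to 1 inside the voxel.
    """
    if mask.shape != maps.shape:
        raise ValueError("mask shape does not match maps")
    wsum = mask.sum()
    if wsum <= 0:
        raise ValueError("empty mask")
    raw = np.array(
        [
            float((mask * maps.prob_gm).sum()),
            float((mask * maps.prob_wm).sum()),
            float((mask * maps.prob_csf).sum()),
        ]
    )
    if raw.sum() < _DEGENERATE_SUM * wsum:
        raise ValueError(
            "insufficient brain coverage: probabilities inside the voxel "
            f"sum to {raw.sum() / wsum:.3f} of the mask on average"
        )
    return normalize_fractions(raw / wsum)


def normalize_fractions(raw) -> TissueFractions:
    """Normalize three nonnegative components to sum exactly to 1."""
    raw = np.asarray(raw, float)
    if raw.shape != (3,):
        raise ValueError("expected three components")
    if np.any(raw < 0):
        raise ValueError("fractions must be nonnegative")
    s = raw.sum()
    if s < _DEGENERATE_SUM:
        raise ValueError(f"degenerate fractions: sum {s:.4g} < {_DEGENERATE_SUM}")
    f = raw / s
    return TissueFractions(float(f[0]), float(f[1]), float(f[2]))
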