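"""Tracheal surface quantification from a binary tube mask.

The surface is extracted by marching cubes at iso-level 0.5 on the binary
voxel mask (anisotropic spacing handled on the grid) and the triangle mesh
is then relaxed with a fixed number of Taubin smoothing passes before the
triangle areas are summed. The mesh smoothing removes the systematic
staircase over-estimate of curved voxelized surfaces (about +8% for a
sphere) while leaving planar faces essentially untouched; it is fully
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from skimage.measure import marching_cubes, mesh_surface_area

from .image_io import RegionMask, Stack
from .segmentation import autothreshold

__all__ = [
    "SurfaceResult",
    "binarize_trachea",
    "surface_area",
    "per_region_surface",
]

log = logging.getLogger(__name__)

TAUBIN_ITERATIONS = 20
TAUBIN_LAMB = 0.5
TAUBIN_NU = 0.53


@dataclass
class SurfaceResult:
    """Per-region tracheal surface areas in µm²."""

    per_region: dict[str, float]
    total: float
    spacing_xy: float
    spacing_z: float


def binarize_trachea(stack: Stack, channel: str, threshold: float | str = "auto") -> np.ndarray:
    """Threshold the tracheal channel; voxels strictly above are foreground.

    ``threshold="auto"`` applies the intermeans threshold to the pooled
    stack histogram; a constant channel raises an error in that case.
    """
    arr = np.asarray(stack.channel(channel))
    if threshold == "auto":
        threshold = autothreshold(arr, "intermeans_default")
    return arr > float(threshold)


def surface_area(mask: np.ndarray, spacing_xy: float, spacing_z: float) -> float:
    """Isosurface area (µm²) of a binary voxel mask on an anisotropic grid."""
    if spacing_xy <= 0 or spacing_z <= 0:
        raise ValueError("spacings must be strictly positive")
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D (sections, rows, cols)")
    if not mask.any():
        return 0.0
    vol = np.pad(mask, 1).astype(np.float64)
    spacing = (spacing_z, spacing_xy, spacing_xy)
    verts, faces, _, _ = marching_cubes(vol, level=0.5, spacing=spacing)
    if len(faces) == 0:
        return 0.0
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    trimesh.smoothing.filter_taubin(
        mesh, lamb=TAUBIN_LAMB, nu=TAUBIN_NU, iterations=TAUBIN_ITERATIONS
    )
    return float(mesh.area)


def per_region_surface(
    mask: np.ndarray,
    region_mask: RegionMask,
    spacing_xy: float,
    spacing_z: float,
) -> SurfaceResult:
    """Surface area of the tracheal mask clipped to each anatomical region.

    Clipping introduces artificial cut faces where tubes cross region
    borders; they are included in the per-region areas and the discrepancy
    against the unclipped whole-mask surface is logged.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != region_mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match region mask shape {region_mask.shape}"
        )
    per_region: dict[str, float] = {}
    for rid, name in sorted(region_mask.names.items()):
        per_region[name] = surface_area(mask & (region_mask.labels == rid), spacing_xy, spacing_z)
    unassigned = surface_area(mask & (region_mask.labels == 0), spacing_xy, spacing_z)
    per_region[RegionMask.UNASSIGNED] = unassigned
    total = float(sum(per_region.values()))
    whole = surface_area(mask, spacing_xy, spacing_z)
    if whole > 0:
        log.info(
            "region clipping: sum of clipped areas %.1f µm² vs whole-mask %.1f µm² "
            "(cut-face contribution %.1f µm²)",
            total, whole, total - whole,
        )
    return SurfaceResult(per_region=per_region, total=total,
                         spacing_xy=spacing_xy, spacing_z=spacing_z)
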