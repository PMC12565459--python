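"""3D shape features of a binary ROI mask (14 values, mask-only).

Mesh-based quantities (volume, surface area, sphericity) come from a
marching-cubes surface of the zero-padded mask; diameters from convex
hulls of surface-voxel physical coordinates; axis lengths from the
eigenvalues of the voxel-coordinate covariance (principal moments).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .registry import SHAPE_FEATURES

__all__ = ["shape_features"]


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise distance; convex hull first when it pays off."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 32 and pts.shape[1] <= 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) point sets
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask)
    surf = mask & ~eroded
    return np.argwhere(surf)


def _max_2d_diameter(coords_phys: np.ndarray, coords_idx: np.ndarray, fixed_axis: int) -> float:
    """Max in-plane diameter over slices perpendicular to ``fixed_axis``."""
    plane_axes = [a for a in range(3) if a != fixed_axis]
    best = 0.0
    for v in np.unique(coords_idx[:, fixed_axis]):
        pts = coords_phys[coords_idx[:, fixed_axis] == v][:, plane_axes]
        best = max(best, _max_pairwise(pts))
    return best


def shape_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """The standard 14 shape descriptors of a 3D binary mask.

    Degenerate ROIs (single voxel, or flat in some axis) fall back to
    zero axis lengths/ratios where the principal moments vanish.
    """
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = float(np.prod(spacing))

    padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    cross = np.cross(v1 - v0, v2 - v0)
    surface_area = float(0.5 * np.linalg.norm(cross, axis=1).sum())
    mesh_volume = float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area

    surf_idx = _surface_voxels(mask)
    if len(surf_idx) == 0:  # single-voxel ROI: the voxel is its own surface
        surf_idx = np.argwhere(mask)
    surf_phys = surf_idx * np.asarray(spacing)

    max3d = _max_pairwise(surf_phys)
    # Plane conventions: Slice = axial (axis 2 fixed), Column = coronal
    # (axis 1 fixed), Row = sagittal (axis 0 fixed).
    max2d_slice = _max_2d_diameter(surf_phys, surf_idx, fixed_axis=2)
    max2d_column = _max_2d_diameter(surf_phys, surf_idx, fixed_axis=1)
    max2d_row = _max_2d_diameter(surf_phys, surf_idx, fixed_axis=0)

    coords = np.argwhere(mask) * np.asarray(spacing)
    if len(coords) > 1:
        eig = np.linalg.eigvalsh(np.cov(coords.T))
        eig = np.clip(eig, 0.0, None)[::-1]  # major, minor, least
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    values = {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n * voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else 0.0,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d_slice,
        "Maximum2DDiameterColumn": max2d_column,
        "Maximum2DDiameterRow": max2d_row,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": elongation,
        "Flatness": flatness,
    }
    return {name: values[name] for name in SHAPE_FEATURES}
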