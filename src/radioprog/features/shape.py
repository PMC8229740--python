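"""3D shape and size descriptors of the ROI mask — 14 features.

Surface quantities come from a marching-cubes mesh of the binary mask in
physical (mm) coordinates; axis lengths from the eigenvalues of the voxel
coordinate covariance (principal-component ellipsoid convention: axis length
= 4 sqrt(lambda)).
"""

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import marching_cubes, mesh_surface_area

SHAPE_FEATURE_NAMES = [
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
]


def _mesh_volume(verts, faces):
    """Signed volume by the divergence theorem over mesh triangles."""
    a = verts[faces[:, 0]]
    b = verts[faces[:, 1]]
    c = verts[faces[:, 2]]
    return abs(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)


def _max_pairwise(points):
    if len(points) < 2:
        return 0.0
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts, qhull_options="QJ").vertices]
        except Exception:
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _max_planar_diameter(coords_mm, group_axis):
    """Largest in-plane vertex distance over planes orthogonal to group_axis."""
    keep = [a for a in range(3) if a != group_axis]
    best = 0.0
    planes = np.unique(coords_mm[:, group_axis])
    for v in planes:
        pts = coords_mm[coords_mm[:, group_axis] == v][:, keep]
        if len(pts) >= 2:
            d = _max_pairwise(pts)
            if d > best:
                best = d
    return best


def shape_features(mask, spacing):
    """Compute the 14 shape features of a binary mask.

    Parameters
    ----------
    mask : 3D bool array, non-empty.
    spacing : (3,) voxel spacing in mm, (x, y, z) matching the array axes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("shape features need a non-empty mask")
    spacing = np.asarray(spacing, dtype=np.float64)
    voxel_volume = float(np.prod(spacing))
    n_vox = int(mask.sum())

    padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area = float(mesh_surface_area(verts, faces))
    volume = float(_mesh_volume(verts, faces))

    sphericity = (36.0 * np.pi * volume * volume) ** (1.0 / 3.0) / area

    coords = np.argwhere(mask).astype(np.float64) * spacing
    # diameters are attained between boundary voxels
    from scipy.ndimage import binary_erosion

    boundary = mask & ~binary_erosion(mask)
    max3d = _max_pairwise(np.argwhere(boundary).astype(np.float64) * spacing)
    # planes indexed by integer voxel coordinate, distances in mm
    vox = np.argwhere(boundary)
    diam = []
    for axis in (2, 1, 0):  # Slice: fixed z; Column: fixed y; Row: fixed x
        keep = [a for a in range(3) if a != axis]
        best = 0.0
        for v in np.unique(vox[:, axis]):
            pts = vox[vox[:, axis] == v][:, keep] * spacing[keep]
            best = max(best, _max_pairwise(pts))
        diam.append(best)
    max2d_slice, max2d_column, max2d_row = diam

    centered = coords - coords.mean(axis=0)
    if n_vox > 1:
        cov = centered.T @ centered / n_vox
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
    else:
        eigvals = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
    elongation = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 1.0
    flatness = float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else 1.0

    return {
        "MeshVolume": volume,
        "VoxelVolume": n_vox * voxel_volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d_slice,
        "Maximum2DDiameterColumn": max2d_column,
        "Maximum2DDiameterRow": max2d_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }
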