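"""2D shape features of the ROI mask in physical (mm) units.

Mesh-based quantities (``MeshSurface``, ``Perimeter``) come from the
marching-squares 0.5-level contour of the padded mask, so surfaces and
perimeters refer to the smoothed iso-contour rather than the blocky
pixel outline; ``PixelSurface`` is the plain pixel count times pixel
area.  Axis lengths follow the principal-component convention:
``MajorAxisLength = 4 * sqrt(lambda_max)`` of the physical-coordinate
covariance (population form), which is exact for a filled ellipse.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

from ..cohort import RoiMask

__all__ = ["shape2d_features"]


def _mesh(mask: np.ndarray, spacing: tuple[float, float]) -> tuple[float, float]:
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5, positive_orientation="high")
    area = 0.0
    perimeter = 0.0
    for contour in contours:
        pts = (contour - 1.0) * np.asarray(spacing)  # physical (row, col) mm
        r, c = pts[:, 0], pts[:, 1]
        # signed shoelace; holes wind opposite to the outer boundary
        area += 0.5 * float(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
        perimeter += float(np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1)).sum())
    return abs(area), perimeter


def shape2d_features(mask: RoiMask, spacing_mm: tuple[float, float]) -> dict[str, float]:
    m = mask.mask
    sr, sc = spacing_mm
    coords = np.argwhere(m).astype(float) * np.asarray([sr, sc])

    mesh_area, perimeter = _mesh(m, (sr, sc))
    pixel_surface = mask.pixel_count * sr * sc

    nan = float("nan")
    major = minor = elong = nan
    if len(coords) > 1:
        cov = np.cov(coords, rowvar=False, ddof=0)
        eigs = np.sort(np.linalg.eigvalsh(cov))  # ascending
        if eigs[-1] > 0:
            major = 4.0 * float(np.sqrt(eigs[-1]))
            minor = 4.0 * float(np.sqrt(max(eigs[0], 0.0)))
            elong = float(np.sqrt(max(eigs[0], 0.0) / eigs[-1]))

    # max pairwise distance between pixel centres, via the convex hull
    if len(coords) >= 3 and not np.allclose(coords, coords[0]):
        try:
            hull_pts = coords[ConvexHull(coords, qhull_options="QJ").vertices]
        except Exception:
            hull_pts = coords
    else:
        hull_pts = coords
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    max_diam = float(np.sqrt((diff**2).sum(axis=2)).max()) if len(hull_pts) > 1 else nan

    sphericity = 2.0 * float(np.sqrt(np.pi * mesh_area)) / perimeter if perimeter > 0 else nan

    return {
        "Elongation": elong,
        "MajorAxisLength": major,
        "MaximumDiameter": max_diam,
        "MeshSurface": mesh_area,
        "MinorAxisLength": minor,
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / mesh_area if mesh_area > 0 else nan,
        "PixelSurface": pixel_surface,
        "Sphericity": sphericity,
    }
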