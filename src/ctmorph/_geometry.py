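"""Shared plane-geometry helpers.

Everything operates in the package's canonical frame: ``x`` = column
(rightward), ``y`` = row (downward, toward posterior on an anterior-up axial
slice).  A positive rotation angle rotates the +x axis toward +y.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def fold_angle_deg(angle: float) -> float:
    """Fold an angle in degrees into the axis convention (-90, 90]."""
    a = float(angle) % 180.0
    if a > 90.0:
        a -= 180.0
    return a


def angle_of_vector_deg(dx: float, dy: float) -> float:
    """Angle of a direction vector versus the +x axis, degrees, in (-180, 180]."""
    return float(np.degrees(np.arctan2(dy, dx)))


def unit_from_angle_deg(angle: float) -> np.ndarray:
    th = np.deg2rad(angle)
    return np.array([np.cos(th), np.sin(th)])


def rotate_points(points: np.ndarray, deg: float, center: tuple[float, float]) -> np.ndarray:
    """Rotate (x, y) points by ``deg`` about ``center`` (positive: +x toward +y)."""
    th = np.deg2rad(deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ctr = np.asarray(center, dtype=float)
    out = (pts - ctr) @ rot.T + ctr
    return out if np.asarray(points).ndim == 2 else out[0]


def rotate_mask_grid(grid: np.ndarray, deg: float) -> np.ndarray:
    """Rotate a boolean grid about its centre so directions shift by +deg.

    Consistent with :func:`rotate_points`: the principal axis of the rotated
    mask sits at (original angle + deg) in the canonical frame.
    """
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    # affine_transform maps output (row, col) to input coords; we need the
    # inverse rotation R(-deg), expressed in (y, x) ordering.
    mat = np.array([[c, -s], [s, c]])
    center = (np.array(grid.shape, dtype=float) - 1) / 2.0
    offset = center - mat @ center
    out = ndimage.affine_transform(grid.astype(float), mat, offset=offset, order=0, mode="constant")
    return out >= 0.5


def rotate_image_grid(image: np.ndarray, deg: float) -> np.ndarray:
    """Same rotation as :func:`rotate_mask_grid` but bilinear, for grayscale."""
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    mat = np.array([[c, -s], [s, c]])
    center = (np.array(image.shape, dtype=float) - 1) / 2.0
    offset = center - mat @ center
    return ndimage.affine_transform(image.astype(float), mat, offset=offset, order=1,
                                    mode="constant", cval=float(np.min(image)))
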