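"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by exhaustive scanning or direct
definition, sharing no code path with the package implementation (no
contour tracing, no scipy ConvexHull, no sklearn metrics).
"""

from __future__ import annotations

import numpy as np


def brute_force_hull(points: np.ndarray) -> set:
    """O(n^3)-style convex hull by definition: a pair of points spans a hull
    edge iff every other point lies on one side of their line; of the points
    collinear with a hull edge only the two extreme ones are vertices.
    Inner test vectorized for tractability."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    verts: set = set()
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pts[i], pts[j]
            d = b - a
            rel = pts - a
            side = np.round(d[0] * rel[:, 1] - d[1] * rel[:, 0], 9)
            nz = side[side != 0]
            if len(nz) == 0 or np.all(nz > 0) or np.all(nz < 0):
                # hull edge (or fully collinear set): only the extreme
                # collinear points are vertices
                collinear = pts[side == 0]
                proj = collinear @ d
                verts.add(tuple(collinear[np.argmin(proj)]))
                verts.add(tuple(collinear[np.argmax(proj)]))
    return verts


def boundary_pixels(grid: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one 4-neighbour outside the mask."""
    g = np.asarray(grid, dtype=bool)
    padded = np.pad(g, 1)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    rc = np.argwhere(g & ~interior)
    return rc[:, ::-1].astype(float)  # (x, y)


def exhaustive_sulcus_region(grid: np.ndarray, ridge_a, ridge_b,
                             band: float = 2.0) -> np.ndarray:
    """Exhaustive boundary scan for the most concave region below the ridge
    chord: every boundary pixel between the ridges is examined directly (no
    contour tracing, no hull machinery), and the pixels within ``band`` mm
    of the maximal perpendicular depth are returned.  The implementation's
    sulcus point must land in (or within a pixel of) this region."""
    b = boundary_pixels(grid)
    lo, hi = sorted([ridge_a[0], ridge_b[0]])
    cy = np.argwhere(grid)[:, 0].mean()
    sel = b[(b[:, 0] > lo) & (b[:, 0] < hi) & (b[:, 1] < cy)]
    a = np.array(ridge_a, dtype=float)
    ch = np.array(ridge_b, dtype=float) - a
    clen = np.linalg.norm(ch)
    rel = sel - a
    depth = np.abs(ch[0] * rel[:, 1] - ch[1] * rel[:, 0]) / clen
    return sel[depth >= depth.max() - band]


def exhaustive_peaks(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Morphological scan for the cup-opening rim points.

    Independent machinery: the defect region is the set difference between
    the filled convex-hull image and the mask; its deepest connected
    component (largest distance-to-mask) is the opening; the rim points are
    the mask pixels that touch both that component and the hull-image
    boundary, clustered into the two tips.  Returns the anterior tip first.
    """
    from scipy import ndimage
    from skimage.morphology import convex_hull_image

    g = np.asarray(grid, dtype=bool)
    hull_img = convex_hull_image(g)
    defects = hull_img & ~g
    lab, n = ndimage.label(defects)
    dt = ndimage.distance_transform_edt(~g)
    depths = ndimage.maximum(dt, lab, index=np.arange(1, n + 1))
    comp = lab == (int(np.argmax(depths)) + 1)
    wall = g & ndimage.binary_dilation(comp, structure=np.ones((3, 3)))
    hull_edge = hull_img & ~ndimage.binary_erosion(hull_img)
    tips = wall & ndimage.binary_dilation(hull_edge, structure=np.ones((3, 3)))
    tl, tn = ndimage.label(tips, structure=np.ones((3, 3)))
    assert tn >= 2, "opening should touch the hull boundary at two tips"
    sizes = ndimage.sum(tips, tl, index=np.arange(1, tn + 1))
    keep = np.argsort(sizes)[-2:] + 1
    pts = []
    ctr = np.argwhere(g)[:, ::-1].mean(axis=0)
    for k in keep:
        xy = np.argwhere(tl == k)[:, ::-1].astype(float)
        pts.append(xy[np.argmax(((xy - ctr) ** 2).sum(axis=1))])  # outermost pixel
    p1, p2 = sorted(pts, key=lambda p: p[1])
    return np.array(p1), np.array(p2)


def brute_force_confusion(y_pred, y_true, n_classes: int = 9) -> np.ndarray:
    out = np.zeros((n_classes, n_classes), dtype=int)
    for p, t in zip(y_pred, y_true):
        out[t, p] += 1
    return out


def permutation_ttest_pvalue(a: np.ndarray, b: np.ndarray, n_perm: int = 10_000,
                             seed: int = 0) -> float:
    """Two-sided paired sign-flip permutation test on the mean difference."""
    rng = np.random.default_rng(seed)
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    observed = abs(d.mean())
    flips = rng.choice([-1.0, 1.0], size=(n_perm, len(d)))
    perm_means = np.abs((flips * d).mean(axis=1))
    return float((np.sum(perm_means >= observed - 1e-12) + 1) / (n_perm + 1))
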