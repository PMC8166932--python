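"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the distance
oracle is pure surface sampling with local grid refinement, the volume
oracle is Monte Carlo point counting.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from mcfperc.geometry import Platelet


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_platelet(
    rng: np.random.Generator,
    pid: int = 0,
    center_scale: float = 2.0,
    dim_range: tuple[float, float] = (0.2, 1.5),
) -> Platelet:
    return Platelet(
        pid,
        rng.uniform(-center_scale, center_scale, 3),
        rng.uniform(*dim_range, 3),
        random_rotation(rng),
    )


def _face_grid(c, R, h, m: int) -> np.ndarray:
    """Points on all 6 faces, m x m per face, grid endpoints included
    (so edges and corners are covered)."""
    pts = []
    lin = [np.linspace(-h[a], h[a], m) for a in range(3)]
    for axis in range(3):
        o1, o2 = (axis + 1) % 3, (axis + 2) % 3
        u, v = np.meshgrid(lin[o1], lin[o2], indexing="ij")
        for sgn in (-1.0, 1.0):
            local = np.zeros((m * m, 3))
            local[:, axis] = sgn * h[axis]
            local[:, o1] = u.ravel()
            local[:, o2] = v.ravel()
            pts.append(local)
    return c + np.vstack(pts) @ R.T


def _local_patch(c, R, h, point, radius: float, m: int) -> np.ndarray:
    """Surface points of the box near `point` (global), on every face,
    restricted to a local window of half-width `radius`."""
    lp = R.T @ (point - c)
    pts = []
    for axis in range(3):
        o1, o2 = (axis + 1) % 3, (axis + 2) % 3
        for sgn in (-1.0, 1.0):
            u = np.linspace(
                max(-h[o1], lp[o1] - radius), min(h[o1], lp[o1] + radius), m
            )
            v = np.linspace(
                max(-h[o2], lp[o2] - radius), min(h[o2], lp[o2] + radius), m
            )
            uu, vv = np.meshgrid(u, v, indexing="ij")
            local = np.zeros((m * m, 3))
            local[:, axis] = sgn * h[axis]
            local[:, o1] = uu.ravel()
            local[:, o2] = vv.ravel()
            pts.append(local)
    return c + np.vstack(pts) @ R.T


def oracle_min_distance(
    a: Platelet, b: Platelet, m_coarse: int = 24, refinements: int = 5
) -> float:
    """Minimum distance by dense surface sampling with local refinement.

    Coarse m x m grids on every face of both boxes (edges and corners
    included), then repeated re-gridding around the current closest
    pair with a shrinking window.
    """
    A = _face_grid(a.centroid, a.orientation, a.half_dims, m_coarse)
    B = _face_grid(b.centroid, b.orientation, b.half_dims, m_coarse)
    D = cdist(A, B)
    i, j = np.unravel_index(np.argmin(D), D.shape)
    best = D[i, j]
    pa, pb = A[i], B[j]
    radius = float(max(np.max(a.half_dims), np.max(b.half_dims))) / m_coarse * 3
    for _ in range(refinements):
        A = _local_patch(a.centroid, a.orientation, a.half_dims, pa, radius, 20)
        B = _local_patch(b.centroid, b.orientation, b.half_dims, pb, radius, 20)
        D = cdist(A, B)
        i, j = np.unravel_index(np.argmin(D), D.shape)
        if D[i, j] < best:
            best = D[i, j]
            pa, pb = A[i], B[j]
        radius /= 4.0
    return float(best)


def oracle_overlap_volume(
    a: Platelet, b: Platelet, rng: np.random.Generator, n: int = 400_000
) -> tuple[float, float]:
    """(estimate, standard error) of the intersection volume by Monte
    Carlo point counting inside box a."""
    local = rng.uniform(-1.0, 1.0, (n, 3)) * a.half_dims
    pts = a.centroid + local @ a.orientation.T
    in_b = np.all(
        np.abs((pts - b.centroid) @ b.orientation) <= b.half_dims, axis=1
    )
    frac = in_b.mean()
    va = float(np.prod(2.0 * a.half_dims))
    est = frac * va
    se = float(np.sqrt(max(frac * (1 - frac), 1e-12) / n) * va)
    return est, se
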