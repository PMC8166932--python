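"""Oriented-platelet geometry in the fibril coordinate frame.

The global frame has axes W and T spanning the equatorial plane of the
fibril and L along its longitudinal axis; all lengths are nanometres.
An apatite platelet is an oriented rectangular parallelepiped; the
fibril is a cylinder of a given diameter and length whose simulation
boundary (the *tolerance cylinder*) is enlarged by a small factor so
that peripheral platelets can rotate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import kernels

__all__ = [
    "Point3",
    "Platelet",
    "FibrilDomain",
    "platelet_vertices",
    "platelet_volume",
    "inside_tolerance_cylinder",
    "min_distance",
    "overlap_volume",
    "inclination_deg",
]

#: Tolerance for orthonormality checks on orientation matrices.
ORTHO_TOL = 1e-9


class Point3(NamedTuple):
    """A point in the global fibril frame (nm)."""

    w: float
    t: float
    l: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("orientation must be a 3x3 matrix")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
        raise ValueError("orientation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("orientation matrix must be a proper rotation")
    return R


@dataclass(frozen=True)
class Platelet:
    """One apatite crystal: an oriented box.

    Parameters
    ----------
    id
        Integer index within a configuration.
    centroid
        Box centre in the global (W, T, L) frame, nm.
    half_dims
        Half-width, half-thickness, half-length (nm); the platelet local
        axes are (width, thickness, length) in that order, so the local
        length axis maps to column 2 of ``orientation``.
    orientation
        3x3 proper rotation mapping platelet local axes to the global
        frame (columns are the local axes expressed globally).
    """

    id: int
    centroid: np.ndarray
    half_dims: np.ndarray
    orientation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )

    def __post_init__(self):
        object.__setattr__(
            self, "centroid", np.asarray(self.centroid, dtype=float)
        )
        hd = np.asarray(self.half_dims, dtype=float)
        if hd.shape != (3,) or np.any(hd <= 0):
            raise ValueError("half_dims must be three positive lengths")
        object.__setattr__(self, "half_dims", hd)
        object.__setattr__(
            self, "orientation", _check_rotation(self.orientation)
        )

    @property
    def dims(self) -> np.ndarray:
        """Full width, thickness, length (nm)."""
        return 2.0 * self.half_dims

    def translated(self, delta: np.ndarray) -> "Platelet":
        return Platelet(
            self.id, self.centroid + np.asarray(delta, float),
            self.half_dims, self.orientation,
        )


@dataclass(frozen=True)
class FibrilDomain:
    """Cylindrical simulation region for the mineralized collagen fibril.

    The nominal cylinder is ``diameter`` x ``length``; the tolerance
    cylinder enlarges both radius and length by ``tolerance_factor``
    (centred, so the longitudinal slack is split between the two ends).
    """

    diameter: float = 50.0
    length: float = 1000.0
    tolerance_factor: float = 1.05

    def __post_init__(self):
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("diameter and length must be positive")
        if self.tolerance_factor < 1.0:
            raise ValueError("tolerance_factor must be >= 1")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def volume(self) -> float:
        """Nominal cylinder volume, nm^3."""
        return np.pi * self.radius**2 * self.length

    @property
    def tolerance_radius(self) -> float:
        return self.tolerance_factor * self.radius

    @property
    def tolerance_l_bounds(self) -> tuple[float, float]:
        slack = 0.5 * (self.tolerance_factor - 1.0) * self.length
        return (-slack, self.length + slack)


def platelet_vertices(p: Platelet) -> np.ndarray:
    """The 8 corners of a platelet, shape (8, 3).

    Corner ``k`` carries local signs ((k>>2)&1, (k>>1)&1, k&1) mapped
    0 -> -1, 1 -> +1 on (width, thickness, length); see
    :mod:`mcfperc.kernels` for the shared convention.
    """
    return kernels.box_vertices(p.centroid, p.orientation, p.half_dims)


def platelet_volume(p: Platelet) -> float:
    """Box volume, nm^3."""
    return float(8.0 * np.prod(p.half_dims))


def inside_tolerance_cylinder(p: Platelet, d: FibrilDomain) -> bool:
    """True iff every vertex lies in the (closed) tolerance cylinder."""
    l_lo, l_hi = d.tolerance_l_bounds
    return bool(
        kernels.inside_cylinder_kernel(
            p.centroid, p.orientation, p.half_dims,
            d.tolerance_radius, l_lo, l_hi,
        )
    )


def min_distance(a: Platelet, b: Platelet) -> float:
    """Minimum Euclidean distance between two platelets (0 if touching
    or interpenetrating).

    The underlying solver alternates exact nearest-point projections
    between the two boxes, which converges to the global minimum for
    convex bodies, with a separating-axis pre-test for the overlapping
    case.
    """
    return float(
        kernels.min_distance_kernel(
            a.centroid, a.orientation, a.half_dims,
            b.centroid, b.orientation, b.half_dims,
        )
    )


def overlap_volume(a: Platelet, b: Platelet) -> float:
    """Interpenetration volume of two platelets, nm^3.

    Exact convex clipping: one box is cut by the six face planes of the
    other and the resulting polytope volume is integrated.  Returns 0
    for disjoint, touching, or degenerate sliver intersections.
    """
    return float(
        kernels.overlap_volume_kernel(
            a.centroid, a.orientation, a.half_dims,
            b.centroid, b.orientation, b.half_dims,
        )
    )


def inclination_deg(p: Platelet) -> float:
    """Angle (degrees, in [0, 90]) between the platelet length axis and
    the fibril longitudinal axis."""
    c = abs(float(p.orientation[2, 2]))
    return float(np.degrees(np.arccos(min(1.0, max(-1.0, c)))))
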