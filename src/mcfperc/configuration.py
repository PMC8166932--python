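"""The Configuration container: one realization of the mineral phase.

Platelet poses are stored as flat arrays (centroids, half-dimensions,
orientation matrices) so that the Monte Carlo and cluster kernels can
operate on them directly; :class:`~mcfperc.geometry.Platelet` views are
constructed on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .geometry import FibrilDomain, Platelet

__all__ = ["Configuration"]


def euler_wtl_from_matrix(R: np.ndarray) -> np.ndarray:
    """Extract (a_W, a_T, a_L) with R = R_L(a_L) @ R_T(a_T) @ R_W(a_W).

    Standard Z-Y-X extraction; valid away from the a_T = +-90 deg gimbal
    singularity, which platelet orientations (inclination-capped well
    below 90 deg) never approach.
    """
    at = -np.arcsin(min(1.0, max(-1.0, R[2, 0])))
    aw = np.arctan2(R[2, 1], R[2, 2])
    al = np.arctan2(R[1, 0], R[0, 0])
    return np.array([aw, at, al])


@dataclass
class Configuration:
    """All platelets of one realization plus bookkeeping state.

    ``angles`` is the canonical orientation state: per-platelet rotation
    angles (radians) about the world W, T, L axes, applied in that
    order; ``orientations`` caches the corresponding matrices for the
    geometry kernels.  When only matrices are supplied the angles are
    recovered by Euler extraction.
    """

    domain: FibrilDomain
    centroids: np.ndarray      # (n, 3)
    half_dims: np.ndarray      # (n, 3)
    orientations: np.ndarray   # (n, 3, 3)
    achieved_vf: float = 0.0
    angles: np.ndarray = field(default=None)  # (n, 3), radians

    def __post_init__(self):
        self.centroids = np.ascontiguousarray(self.centroids, dtype=float)
        self.half_dims = np.ascontiguousarray(self.half_dims, dtype=float)
        self.orientations = np.ascontiguousarray(
            self.orientations, dtype=float
        )
        n = self.centroids.shape[0]
        if self.half_dims.shape != (n, 3):
            raise ValueError("half_dims shape mismatch")
        if self.orientations.shape != (n, 3, 3):
            raise ValueError("orientations shape mismatch")
        if self.angles is None:
            self.angles = np.stack(
                [euler_wtl_from_matrix(self.orientations[i]) for i in range(n)]
            ) if n else np.zeros((0, 3))
        self.angles = np.ascontiguousarray(self.angles, dtype=float)
        if self.angles.shape != (n, 3):
            raise ValueError("angles shape mismatch")

    # -- construction ------------------------------------------------

    @classmethod
    def from_platelets(
        cls, domain: FibrilDomain, platelets: list[Platelet]
    ) -> "Configuration":
        n = len(platelets)
        c = np.zeros((n, 3))
        h = np.zeros((n, 3))
        R = np.zeros((n, 3, 3))
        for k, p in enumerate(platelets):
            c[k] = p.centroid
            h[k] = p.half_dims
            R[k] = p.orientation
        vf = float(8.0 * np.prod(h, axis=1).sum() / domain.volume)
        return cls(domain, c, h, R, achieved_vf=vf)

    # -- views -------------------------------------------------------

    @property
    def n_platelets(self) -> int:
        return self.centroids.shape[0]

    @property
    def volumes(self) -> np.ndarray:
        """Per-platelet volume, nm^3."""
        return 8.0 * np.prod(self.half_dims, axis=1)

    @property
    def min_dims(self) -> np.ndarray:
        """Per-platelet smallest full dimension (the thickness), nm."""
        return 2.0 * np.min(self.half_dims, axis=1)

    def platelet(self, i: int) -> Platelet:
        return Platelet(
            i, self.centroids[i], self.half_dims[i], self.orientations[i]
        )

    @property
    def platelets(self) -> list[Platelet]:
        return [self.platelet(i) for i in range(self.n_platelets)]

    def aabbs(self) -> np.ndarray:
        """(n, 2, 3) per-platelet axis-aligned bounds."""
        return kernels.all_aabbs(
            self.centroids, self.orientations, self.half_dims
        )

    def vertices(self, i: int) -> np.ndarray:
        return kernels.box_vertices(
            self.centroids[i], self.orientations[i], self.half_dims[i]
        )

    def copy(self) -> "Configuration":
        return Configuration(
            self.domain,
            self.centroids.copy(),
            self.half_dims.copy(),
            self.orientations.copy(),
            self.achieved_vf,
            self.angles.copy(),
        )
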