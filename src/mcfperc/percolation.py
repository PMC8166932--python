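"""Spanning-cluster detection and percolation-curve estimation.

A cluster percolates in a direction when its vertex extent reaches a
direction-specific threshold: in the equatorial plane the cluster must
additionally reach the fibril periphery (some vertex outside 90 % of
the diameter) and its W (or T) extent must reach the minimum chord
length; in the longitudinal direction either the extent reaches the
reduced experimental fibril length, or - in full-length mode - the
cluster has vertices in both 2.5 %-length end caps of the cylinder.

Percolation probability per volume fraction is the fraction of
realizations with at least one spanning cluster; the curve P(VF) is
fitted with P = (1/2)[1 + tanh((VF - VF_c)/Delta)], so the fitted curve
equals 0.5 at the critical volume fraction VF_c by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .clustering import ClusterSet
from .configuration import Configuration
from .geometry import FibrilDomain

__all__ = [
    "SpanningThresholds",
    "FitResult",
    "PercolationCurve",
    "cluster_extent",
    "passes_ring_filter",
    "is_percolating",
    "spanning_directions",
    "percolation_probability",
    "fit_curve",
    "tanh_curve",
]

_AXIS = {"W": 0, "T": 1, "L": 2}

#: Direction-specific spanning lengths (nm) identified for the two
#: fibril diameters: (W_percolation, T_percolation, L_cluster).
_THRESHOLDS_BY_DIAMETER = {50.0: (50.0, 25.0, 300.0),
                           200.0: (120.0, 50.0, 450.0)}


@dataclass(frozen=True)
class SpanningThresholds:
    """Spanning criteria for one fibril geometry.

    w_percolation / t_percolation are minimum chord lengths in the
    equatorial plane, l_cluster the reduced-length longitudinal
    threshold; ring_fraction defines the peripheral filter circle and
    cap_fraction the full-length cap cylinder.  full_length_mode
    switches the L test from reduced-length extent to both-end-caps.
    min_cluster_size excludes small aggregates from the spanning tests:
    the percolation transition is bistable only for clusters of more
    than four platelets, so stray pairs or tilted single crystals that
    happen to reach a chord threshold do not count as spanning.
    """

    w_percolation: float = 50.0
    t_percolation: float = 25.0
    l_cluster: float = 300.0
    ring_fraction: float = 0.9
    cap_fraction: float = 0.95
    full_length_mode: bool = False
    min_cluster_size: int = 5

    @classmethod
    def for_domain(
        cls, domain: FibrilDomain, full_length_mode: bool = False
    ) -> "SpanningThresholds":
        """Thresholds for the studied 50 nm / 200 nm fibrils; other
        diameters fall back to (diameter, diameter/2, 0.3 * length)."""
        key = float(domain.diameter)
        if key in _THRESHOLDS_BY_DIAMETER:
            w, t, l = _THRESHOLDS_BY_DIAMETER[key]
        else:
            w, t, l = (
                domain.diameter, 0.5 * domain.diameter, 0.3 * domain.length
            )
        return cls(w, t, l, full_length_mode=full_length_mode)


def _cluster_vertices(
    cfg: Configuration, cluster: Sequence[int]
) -> np.ndarray:
    """All vertices of a cluster's platelets, shape (8*m, 3)."""
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    return np.concatenate([cfg.vertices(i) for i in cluster], axis=0)


def cluster_extent(
    cfg: Configuration, cluster: Sequence[int], axis: str
) -> tuple[float, float, float]:
    """(min, max, extent) of cluster vertex coordinates along W, T or L."""
    verts = _cluster_vertices(cfg, cluster)
    coords = verts[:, _AXIS[axis]]
    lo, hi = float(coords.min()), float(coords.max())
    return lo, hi, hi - lo


def passes_ring_filter(
    cfg: Configuration,
    cluster: Sequence[int],
    thresholds: SpanningThresholds,
) -> bool:
    """True iff some vertex lies strictly outside the circle of diameter
    ring_fraction * fibril diameter (the cluster reaches the periphery)."""
    verts = _cluster_vertices(cfg, cluster)
    r = thresholds.ring_fraction * cfg.domain.radius
    return bool(np.any(verts[:, 0] ** 2 + verts[:, 1] ** 2 > r * r))


def is_percolating(
    cfg: Configuration,
    cluster: Sequence[int],
    direction: str,
    thresholds: SpanningThresholds,
) -> bool:
    """Spanning test for one cluster in direction "W", "T" or "L"."""
    if direction not in _AXIS:
        raise ValueError(f"unknown direction {direction!r}")
    if len(cluster) < thresholds.min_cluster_size:
        return False
    verts = _cluster_vertices(cfg, cluster)
    if direction in ("W", "T"):
        r = thresholds.ring_fraction * cfg.domain.radius
        if not np.any(verts[:, 0] ** 2 + verts[:, 1] ** 2 > r * r):
            return False
        coords = verts[:, _AXIS[direction]]
        need = (
            thresholds.w_percolation
            if direction == "W"
            else thresholds.t_percolation
        )
        return bool(coords.max() - coords.min() >= need)
    # longitudinal
    l = verts[:, 2]
    if thresholds.full_length_mode:
        # mirror of the equatorial test: boundary filter (vertices
        # outside the central 95%-length cylinder, i.e. in an end cap)
        # plus extent >= the full fibril length; the extent condition
        # forces presence in both end caps
        cap = 0.5 * (1.0 - thresholds.cap_fraction) * cfg.domain.length
        if not (np.any(l < cap) or np.any(l > cfg.domain.length - cap)):
            return False
        return bool(l.max() - l.min() >= cfg.domain.length)
    return bool(l.max() - l.min() >= thresholds.l_cluster)


def spanning_directions(
    cfg: Configuration,
    clusters: ClusterSet,
    thresholds: SpanningThresholds,
) -> dict[str, bool]:
    """Whether any cluster spans the fibril, per direction."""
    out = {"W": False, "T": False, "L": False}
    for cluster in clusters.clusters:
        for d in out:
            if not out[d] and is_percolating(cfg, cluster, d, thresholds):
                out[d] = True
        if all(out.values()):
            break
    return out


def percolation_probability(
    outcomes: Sequence[bool],
) -> tuple[float, float]:
    """P = n_p / N over realizations, with its binomial standard error."""
    if len(outcomes) == 0:
        raise ValueError("no realizations")
    n = len(outcomes)
    p = float(np.count_nonzero(outcomes)) / n
    se = float(np.sqrt(p * (1.0 - p) / n))
    return p, se


def tanh_curve(vf: np.ndarray, vf_c: float, delta: float) -> np.ndarray:
    """P(VF) = (1/2) [1 + tanh((VF - VF_c) / Delta)]."""
    return 0.5 * (1.0 + np.tanh((np.asarray(vf, float) - vf_c) / delta))


@dataclass(frozen=True)
class FitResult:
    """Fitted percolation curve parameters.

    status is "ok", "not_converged" (parameters from the last iterate,
    use with care) or "no_transition" (all-0 or all-1 probabilities:
    the fit is refused and vf_c / delta are None).
    """

    vf_c: float | None
    delta: float | None
    status: str
    cov: np.ndarray | None = None
    vf_c_empirical: float | None = None

    def evaluate(self, vf) -> np.ndarray:
        if self.vf_c is None:
            raise ValueError(f"no fitted curve (status={self.status})")
        return tanh_curve(vf, self.vf_c, self.delta)


def binomial_weights(P: np.ndarray, N) -> np.ndarray:
    """Inverse binomial-variance weights with variance floored at
    1/(4N) so P in {0, 1} does not get infinite weight."""
    P = np.asarray(P, float)
    N = np.asarray(N, float)
    var = np.maximum(P * (1.0 - P) / N, 1.0 / (4.0 * N))
    return 1.0 / var


def fit_curve(
    vf_grid,
    P_values,
    weights=None,
    n_realizations=None,
) -> FitResult:
    """Weighted nonlinear least-squares fit of the tanh percolation curve.

    weights default to inverse binomial variance (floored) when
    n_realizations is given, else uniform.  Initial VF_c is the grid
    point with P nearest 0.5 and initial Delta a quarter of the grid
    span; Delta is constrained positive.  Exact 0/1 probabilities are
    retained; an all-0 or all-1 vector is refused ("no_transition").
    """
    vf = np.asarray(vf_grid, float)
    P = np.asarray(P_values, float)
    if vf.size != P.size:
        raise ValueError("vf_grid and P_values must have equal length")
    if vf.size < 3 or np.ptp(vf) == 0.0:
        raise ValueError("need >= 3 VF points with non-degenerate spread")
    if np.all(P == 0.0) or np.all(P == 1.0):
        return FitResult(None, None, "no_transition")
    if weights is None:
        if n_realizations is not None:
            weights = binomial_weights(P, n_realizations)
        else:
            weights = np.ones_like(P)
    w = np.sqrt(np.asarray(weights, float))

    span = float(np.ptp(vf))
    x0 = np.array([vf[np.argmin(np.abs(P - 0.5))], span / 4.0])

    def resid(x):
        return w * (tanh_curve(vf, x[0], x[1]) - P)

    res = least_squares(
        resid,
        x0,
        bounds=([vf.min() - span, 1e-6], [vf.max() + span, 10.0 * span]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=2000,
    )
    status = "ok" if res.status > 0 else "not_converged"
    # covariance from the weighted Jacobian at the solution
    cov = None
    try:
        JTJ = res.jac.T @ res.jac
        cov = np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        pass
    crossing = np.nonzero(P >= 0.5)[0]
    vf_c_emp = float(vf[crossing[0]]) if crossing.size else None
    return FitResult(
        float(res.x[0]), float(res.x[1]), status, cov, vf_c_emp
    )


@dataclass
class PercolationCurve:
    """Estimated percolation probabilities over a VF grid plus the fit."""

    vf_grid: np.ndarray
    n_p: np.ndarray
    N: np.ndarray
    direction: str = ""
    mode: str = ""
    fit: FitResult | None = None

    def __post_init__(self):
        self.vf_grid = np.asarray(self.vf_grid, float)
        self.n_p = np.asarray(self.n_p, int)
        self.N = np.asarray(self.N, int)
        if np.any(self.n_p > self.N) or np.any(self.n_p < 0):
            raise ValueError("need 0 <= n_p <= N")

    @property
    def P(self) -> np.ndarray:
        return self.n_p / self.N

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.P * (1.0 - self.P) / self.N)

    def fitted(self) -> "PercolationCurve":
        self.fit = fit_curve(self.vf_grid, self.P, n_realizations=self.N)
        return self
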