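"""Athermal Metropolis dynamics for the platelet configuration.

Each trial move displaces one platelet by uniform amounts in [-tau, tau]
along each global axis and rotates it about the W, T, L axes (in that
fixed order) by Gaussian angles of standard deviation theta.  A move is
legal - and always accepted - when the platelet stays inside the
tolerance cylinder, no pairwise interpenetration exceeds 10 % of the
smaller platelet volume, and (by default) the platelet length axis stays
within 20 degrees of the fibril axis.  There is no Boltzmann weighting:
the acceptance rule is purely geometric.

During a cycle the orientation of each platelet is tracked as its
world-axis angle triple (see :class:`~mcfperc.configuration.Configuration`);
trial rotations step these angles, and by default each angle is confined
to +-20 degrees, mirroring the near-alignment of the apatite c-axis
texture with the fibril axis.  Proposals leaving the angle box are
rejected like any other illegal move.

After every cycle (one attempt per platelet) the step sizes adapt by
+/-10 % toward an acceptance ratio of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import kernels
from .configuration import Configuration
from .geometry import Platelet

__all__ = [
    "StepSizes",
    "MoveRules",
    "CycleStats",
    "trial_move",
    "is_acceptable",
    "run_cycle",
    "equilibrate",
    "sample_realizations",
    "audit_configuration",
]


@dataclass(frozen=True)
class StepSizes:
    """Adaptive perturbation amplitudes.

    tau is the maximum translation step (nm), theta the rotation
    standard deviation (degrees); both are capped to keep the adaptive
    rule from running away on very mobile systems.
    """

    tau: float = 1.0
    theta: float = 2.0
    tau_cap: float = 5.0
    theta_cap: float = 10.0

    def __post_init__(self):
        if self.tau <= 0 or self.theta <= 0:
            raise ValueError("step sizes must be positive")

    def adapted(self, acceptance_ratio: float) -> "StepSizes":
        """+10 % when more than half the moves were accepted, else -10 %."""
        f = 1.1 if acceptance_ratio > 0.5 else 0.9
        return replace(
            self,
            tau=min(self.tau * f, self.tau_cap),
            theta=min(self.theta * f, self.theta_cap),
        )


@dataclass(frozen=True)
class MoveRules:
    """Legality rules for trial moves.

    max_overlap_frac bounds pairwise interpenetration volume relative to
    the smaller platelet of the pair.  max_depth_frac additionally
    bounds the pairwise penetration *depth* relative to the smaller
    platelet's thinnest dimension: crystal coalescence is a shallow
    surface fusion, platelets may interpenetrate at their faces but not
    pass through one another (None disables, leaving the volume bound
    alone).  inclination_cap_deg limits the angle between the platelet
    length axis and the fibril axis (None disables the cap).
    angle_cap_deg bounds each of the three world-axis orientation
    angles: platelets stay co-aligned with the fibril frame to within
    this range (the crystallographic c-axis texture of apatite); None
    lets orientations random-walk freely.  texture_sigma_deg is the
    dispersion of the Gaussian orientation texture about perfect
    alignment (the stationary angle distribution, enforced by a
    Metropolis-Hastings factor): a few degrees, consistent with the
    chord thresholds just excluding tilted sub-5-platelet aggregates;
    None gives a flat orientation measure over the angle box.
    """

    max_overlap_frac: float = 0.10
    max_depth_frac: float | None = 0.10
    inclination_cap_deg: float | None = 20.0
    angle_cap_deg: float | None = 20.0
    texture_sigma_deg: float | None = 2.0

    @property
    def min_cos_incl(self) -> float:
        # negative sentinel disables the check in the kernel
        if self.inclination_cap_deg is None:
            return -1.0
        return float(np.cos(np.radians(self.inclination_cap_deg)))

    @property
    def angle_cap_rad(self) -> float:
        if self.angle_cap_deg is None:
            return -1.0
        return float(np.radians(self.angle_cap_deg))

    @property
    def depth_frac(self) -> float:
        return -1.0 if self.max_depth_frac is None else self.max_depth_frac

    @property
    def texture_sigma_rad(self) -> float:
        if self.texture_sigma_deg is None:
            return -1.0
        return float(np.radians(self.texture_sigma_deg))


@dataclass(frozen=True)
class CycleStats:
    proposed: int
    accepted: int
    tau: float
    theta: float

    @property
    def acceptance_ratio(self) -> float:
        return self.accepted / self.proposed if self.proposed else 0.0


def trial_move(
    p: Platelet, s: StepSizes, rng: np.random.Generator
) -> Platelet:
    """One candidate pose: translation then W/T/L rotations; p unmodified."""
    delta = rng.uniform(-s.tau, s.tau, 3)
    angles = np.radians(rng.normal(0.0, s.theta, 3))
    R = kernels.compose_rotation(
        p.orientation, angles[0], angles[1], angles[2]
    )
    return Platelet(p.id, p.centroid + delta, p.half_dims, R)


def is_acceptable(
    candidate: Platelet,
    cfg: Configuration,
    rules: MoveRules = MoveRules(),
) -> bool:
    """Legality of a candidate pose replacing platelet candidate.id.

    True iff the candidate is inside the tolerance cylinder, within the
    inclination cap, and every pairwise interpenetration stays at or
    below max_overlap_frac of the smaller platelet volume.
    """
    l_lo, l_hi = cfg.domain.tolerance_l_bounds
    return bool(
        kernels.candidate_acceptable(
            candidate.id,
            np.ascontiguousarray(candidate.centroid, float),
            np.ascontiguousarray(candidate.orientation, float),
            cfg.centroids,
            cfg.orientations,
            cfg.half_dims,
            cfg.volumes,
            cfg.min_dims,
            cfg.aabbs(),
            cfg.domain.tolerance_radius,
            l_lo,
            l_hi,
            rules.max_overlap_frac,
            rules.depth_frac,
            rules.min_cos_incl,
        )
    )


def _cycle_inplace(
    cfg: Configuration,
    volumes: np.ndarray,
    aabbs: np.ndarray,
    s: StepSizes,
    rng: np.random.Generator,
    rules: MoveRules,
) -> CycleStats:
    """One cycle mutating cfg arrays; random draws are vectorized per
    cycle (all translations, then all rotation angles)."""
    n = cfg.n_platelets
    if n == 0:
        return CycleStats(0, 0, s.tau, s.theta)
    trans = rng.uniform(-s.tau, s.tau, (n, 3))
    dangles = np.radians(rng.normal(0.0, s.theta, (n, 3)))
    mh_u = rng.uniform(0.0, 1.0, n)
    l_lo, l_hi = cfg.domain.tolerance_l_bounds
    accepted = kernels.run_cycle_kernel(
        cfg.centroids,
        cfg.orientations,
        cfg.angles,
        cfg.half_dims,
        volumes,
        cfg.min_dims,
        aabbs,
        trans,
        dangles,
        mh_u,
        rules.angle_cap_rad,
        rules.texture_sigma_rad,
        cfg.domain.tolerance_radius,
        l_lo,
        l_hi,
        rules.max_overlap_frac,
        rules.depth_frac,
        rules.min_cos_incl,
    )
    return CycleStats(n, int(accepted), s.tau, s.theta)


def run_cycle(
    cfg: Configuration,
    s: StepSizes,
    rng: np.random.Generator,
    rules: MoveRules = MoveRules(),
) -> tuple[Configuration, StepSizes, CycleStats]:
    """One Monte Carlo cycle: every platelet attempted once in index
    order; rejected moves keep the prior pose.  Returns the new
    configuration, the adapted step sizes and the cycle statistics."""
    out = cfg.copy()
    stats = _cycle_inplace(out, out.volumes, out.aabbs(), s, rng, rules)
    return out, s.adapted(stats.acceptance_ratio), stats


def equilibrate(
    cfg: Configuration,
    n_cycles: int,
    s: StepSizes,
    rng: np.random.Generator,
    rules: MoveRules = MoveRules(),
) -> tuple[Configuration, StepSizes, list[CycleStats]]:
    """Apply n_cycles adaptive cycles; returns (configuration, step
    sizes, per-cycle trace)."""
    out = cfg.copy()
    volumes = out.volumes
    aabbs = out.aabbs()
    trace: list[CycleStats] = []
    for _ in range(n_cycles):
        stats = _cycle_inplace(out, volumes, aabbs, s, rng, rules)
        s = s.adapted(stats.acceptance_ratio)
        trace.append(stats)
    return out, s, trace


def sample_realizations(
    cfg: Configuration,
    n_snapshots: int,
    thinning_cycles: int,
    s: StepSizes,
    rng: np.random.Generator,
    rules: MoveRules = MoveRules(),
) -> tuple[list[Configuration], StepSizes, list[CycleStats]]:
    """Take n_snapshots deep-copied configurations, one every
    thinning_cycles cycles; each snapshot is one realization entering
    the percolation-probability estimate."""
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    out = cfg.copy()
    volumes = out.volumes
    aabbs = out.aabbs()
    trace: list[CycleStats] = []
    snapshots: list[Configuration] = []
    for _ in range(n_snapshots):
        for _ in range(thinning_cycles):
            stats = _cycle_inplace(out, volumes, aabbs, s, rng, rules)
            s = s.adapted(stats.acceptance_ratio)
            trace.append(stats)
        snapshots.append(out.copy())
    return snapshots, s, trace


def audit_configuration(
    cfg: Configuration, rules: MoveRules = MoveRules()
) -> dict:
    """Full O(n^2) legality audit of a configuration.

    Returns the worst pairwise overlap volume fraction (relative to the
    smaller platelet), the worst penetration-depth fraction (relative
    to the smaller platelet's thinnest dimension), the number of pairs
    above either bound, and whether all platelets lie inside the
    tolerance cylinder.
    """
    n = cfg.n_platelets
    vols = cfg.volumes
    mind = cfg.min_dims
    l_lo, l_hi = cfg.domain.tolerance_l_bounds
    worst = 0.0
    worst_depth = 0.0
    violations = 0
    for i in range(n):
        for j in range(i + 1, n):
            v = kernels.overlap_volume_kernel(
                cfg.centroids[i], cfg.orientations[i], cfg.half_dims[i],
                cfg.centroids[j], cfg.orientations[j], cfg.half_dims[j],
            )
            frac = v / min(vols[i], vols[j])
            worst = max(worst, frac)
            bad = frac > rules.max_overlap_frac + 1e-9
            if rules.max_depth_frac is not None:
                depth = kernels.penetration_depth_kernel(
                    cfg.centroids[i], cfg.orientations[i], cfg.half_dims[i],
                    cfg.centroids[j], cfg.orientations[j], cfg.half_dims[j],
                )
                dfrac = depth / min(mind[i], mind[j])
                worst_depth = max(worst_depth, dfrac)
                bad = bad or dfrac > rules.max_depth_frac + 1e-9
            if bad:
                violations += 1
    inside = all(
        kernels.inside_cylinder_kernel(
            cfg.centroids[i], cfg.orientations[i], cfg.half_dims[i],
            cfg.domain.tolerance_radius, l_lo, l_hi,
        )
        for i in range(n)
    )
    return {
        "max_overlap_fraction": worst,
        "max_depth_fraction": worst_depth,
        "n_overlap_violations": violations,
        "all_inside_tolerance": bool(inside),
    }
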