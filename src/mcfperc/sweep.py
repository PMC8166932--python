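"""End-to-end percolation sweeps over the volume-fraction grid.

For each VF an initial staggered configuration is built, equilibrated
with the adaptive Metropolis dynamics, and sampled into N thinned
snapshots (the realizations).  Every snapshot is analysed once: a
single pair table (distances + overlap volumes within the hydrated-
shell reach) feeds both connectivity criteria, clusters are extracted
with union-find, and spanning is tested in W, T and L (both the
reduced-length and the full-length variant).  The per-VF spanning
fractions give the percolation curves, which are then fitted with the
tanh transition.

Realizations at each VF are split over several independent Markov
chains, each with its own packed initial state and equilibration, so
that the binomial error model for P = n_p / N is not undermined by a
single shared packing.  Default Monte Carlo budgets are desk-scale (a
few thousand cycles and tens of realizations per VF); all are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .clustering import (
    ConnectivityCriterion,
    build_clusters,
    pair_table,
)
from .configuration import Configuration
from .geometry import FibrilDomain
from .lattice import DEFAULT_VF_GRID, DimensionRanges, initialize_configuration
from .metropolis import MoveRules, StepSizes, equilibrate, sample_realizations
from .percolation import (
    PercolationCurve,
    SpanningThresholds,
    is_percolating,
)

__all__ = ["SweepConfig", "SweepResult", "run_sweep", "analyze_snapshot"]


def _split(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]

MODES = ("shell", "interpenetration")
DIRECTION_KEYS = ("W", "T", "L_reduced", "L_full")


@dataclass(frozen=True)
class SweepConfig:
    """All parameters of one percolation sweep (one diameter)."""

    diameter: float = 50.0
    length: float = 1000.0
    vf_grid: tuple = DEFAULT_VF_GRID
    n_realizations: int = 50
    n_chains: int = 5
    equil_cycles: int = 2000
    thinning: int = 10
    seed: int = 0
    delta: float = 1.4
    max_overlap_frac: float = 0.10
    max_depth_frac: float | None = 0.10
    inclination_cap_deg: float | None = 20.0
    angle_cap_deg: float | None = 20.0
    texture_sigma_deg: float | None = 2.0
    tau0: float = 1.0
    theta0: float = 2.0
    clearance: float = 0.4
    include_overlapping_in_shell: bool = True

    def move_rules(self) -> MoveRules:
        return MoveRules(
            max_overlap_frac=self.max_overlap_frac,
            max_depth_frac=self.max_depth_frac,
            inclination_cap_deg=self.inclination_cap_deg,
            angle_cap_deg=self.angle_cap_deg,
            texture_sigma_deg=self.texture_sigma_deg,
        )

    def domain(self) -> FibrilDomain:
        return FibrilDomain(self.diameter, self.length)

    def manifest(self) -> dict:
        return asdict(self)


@dataclass
class SweepResult:
    """Curves keyed by (mode, direction key), plus per-VF diagnostics."""

    config: SweepConfig
    curves: dict[tuple[str, str], PercolationCurve]
    achieved_vf: np.ndarray
    n_platelets: np.ndarray
    final_acceptance: np.ndarray  # time-avg ratio over last 20 % of cycles

    def curve(self, mode: str, direction: str) -> PercolationCurve:
        return self.curves[(mode, direction)]


def analyze_snapshot(
    cfg: Configuration,
    delta: float,
    thresholds_reduced: SpanningThresholds,
    thresholds_full: SpanningThresholds,
    include_overlapping_in_shell: bool = True,
) -> dict[tuple[str, str], bool]:
    """Spanning outcome of one realization for every (mode, direction).

    One pair table within reach=delta serves both criteria: shell edges
    are pairs with d <= delta (overlapping pairs included by default),
    interpenetration edges are pairs with positive overlap volume.
    """
    ii, jj, dd, vv = pair_table(cfg, delta)
    shell_edges = []
    interp_edges = []
    for i, j, d, v in zip(ii, jj, dd, vv):
        if v > 0.0:
            interp_edges.append((int(i), int(j)))
            if include_overlapping_in_shell:
                shell_edges.append((int(i), int(j)))
        elif d <= delta:
            shell_edges.append((int(i), int(j)))
    n = cfg.n_platelets
    out: dict[tuple[str, str], bool] = {}
    for mode, edges in (
        ("shell", shell_edges),
        ("interpenetration", interp_edges),
    ):
        clusters = build_clusters(n, edges)
        span = {k: False for k in DIRECTION_KEYS}
        for cluster in clusters.clusters:
            if not span["W"] and is_percolating(
                cfg, cluster, "W", thresholds_reduced
            ):
                span["W"] = True
            if not span["T"] and is_percolating(
                cfg, cluster, "T", thresholds_reduced
            ):
                span["T"] = True
            if not span["L_reduced"] and is_percolating(
                cfg, cluster, "L", thresholds_reduced
            ):
                span["L_reduced"] = True
            if not span["L_full"] and is_percolating(
                cfg, cluster, "L", thresholds_full
            ):
                span["L_full"] = True
            if all(span.values()):
                break
        for k, v in span.items():
            out[(mode, k)] = v
    return out


def run_sweep(
    config: SweepConfig,
    ranges: DimensionRanges = DimensionRanges(),
    progress: bool = False,
) -> SweepResult:
    """Run the full sweep over the VF grid and fit all curves."""
    domain = config.domain()
    thresholds_reduced = SpanningThresholds.for_domain(domain)
    thresholds_full = SpanningThresholds.for_domain(
        domain, full_length_mode=True
    )
    rules = config.move_rules()
    root_ss = np.random.SeedSequence(config.seed)
    vf_seeds = root_ss.spawn(len(config.vf_grid))

    counts = {
        (mode, key): np.zeros(len(config.vf_grid), dtype=int)
        for mode in MODES
        for key in DIRECTION_KEYS
    }
    achieved = np.zeros(len(config.vf_grid))
    n_platelets = np.zeros(len(config.vf_grid), dtype=int)
    final_acc = np.zeros(len(config.vf_grid))

    for k, vf in enumerate(config.vf_grid):
        # independent Markov chains per VF: each gets a fresh packing,
        # its own equilibration and an equal share of the realizations
        chain_seeds = vf_seeds[k].spawn(config.n_chains)
        per_chain = _split(config.n_realizations, config.n_chains)
        acc_tail = []
        vf_ach = []
        n_pl = []
        for chain, n_snap in enumerate(per_chain):
            if n_snap == 0:
                continue
            rng = np.random.default_rng(chain_seeds[chain])
            cfg = initialize_configuration(
                domain, ranges, None, vf, rng, clearance=config.clearance
            )
            vf_ach.append(cfg.achieved_vf)
            n_pl.append(cfg.n_platelets)
            steps = StepSizes(tau=config.tau0, theta=config.theta0)
            cfg, steps, trace = equilibrate(
                cfg, config.equil_cycles, steps, rng, rules
            )
            snapshots, steps, trace2 = sample_realizations(
                cfg, n_snap, config.thinning, steps, rng, rules
            )
            tail = trace + trace2
            tail = tail[-max(1, len(tail) // 5):]
            acc_tail.extend(t.acceptance_ratio for t in tail)
            for snap in snapshots:
                span = analyze_snapshot(
                    snap,
                    config.delta,
                    thresholds_reduced,
                    thresholds_full,
                    config.include_overlapping_in_shell,
                )
                for key, hit in span.items():
                    if hit:
                        counts[key][k] += 1
        achieved[k] = float(np.mean(vf_ach))
        n_platelets[k] = int(round(np.mean(n_pl)))
        final_acc[k] = float(np.mean(acc_tail))
        if progress:
            print(
                f"VF {vf:.2f}: n={n_platelets[k]} "
                f"acc={final_acc[k]:.2f} "
                f"shellW={counts[('shell', 'W')][k]}/"
                f"{config.n_realizations} "
                f"intW={counts[('interpenetration', 'W')][k]}/"
                f"{config.n_realizations}"
            )

    N = np.full(len(config.vf_grid), config.n_realizations, dtype=int)
    curves = {}
    for key, n_p in counts.items():
        curves[key] = PercolationCurve(
            np.asarray(config.vf_grid), n_p, N,
            direction=key[1], mode=key[0],
        ).fitted()
    return SweepResult(
        config, curves, achieved, n_platelets, final_acc
    )
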