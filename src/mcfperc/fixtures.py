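"""Deterministic toy scenes and seeded small-scale scenarios.

Chain scenes place collinear boxes with an exactly controlled surface
gap (negative gap = controlled slab overlap), which makes cluster and
spanning outcomes hand-verifiable; small-sweep bundles freeze every
parameter and seed of a desk-scale end-to-end run.
"""

from __future__ import annotations

import numpy as np

from .configuration import Configuration
from .geometry import FibrilDomain, Platelet, inside_tolerance_cylinder
from .lattice import DEFAULT_VF_GRID
from .sweep import SweepConfig

__all__ = ["make_chain_scene", "make_small_sweep"]

_AXIS = {"W": 0, "T": 1, "L": 2}


def make_chain_scene(
    direction: str,
    n_boxes: int,
    gap: float,
    domain: FibrilDomain | None = None,
    box_dims: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Configuration:
    """Collinear axis-aligned boxes with pairwise surface gap ``gap``.

    The chain runs along the given direction, centred on the fibril
    axis at mid-length.  box_dims are full (W, T, L) dimensions.  With
    gap < 0 each adjacent pair overlaps by a slab of volume
    |gap| * (product of the other two dimensions).
    """
    if n_boxes < 1:
        raise ValueError("n_boxes must be >= 1")
    if domain is None:
        domain = FibrilDomain()
    axis = _AXIS[direction]
    dims = np.asarray(box_dims, float)
    pitch = dims[axis] + gap
    if n_boxes > 1 and pitch <= 0:
        raise ValueError("overlap may not exceed the box dimension")
    span = dims[axis] + (n_boxes - 1) * pitch
    center = np.array([0.0, 0.0, 0.5 * domain.length])
    start = center[axis] - 0.5 * span + 0.5 * dims[axis]
    platelets = []
    for k in range(n_boxes):
        c = center.copy()
        c[axis] = start + k * pitch
        platelets.append(Platelet(k, c, 0.5 * dims))
    cfg = Configuration.from_platelets(domain, platelets)
    for p in cfg.platelets:
        if not inside_tolerance_cylinder(p, domain):
            raise ValueError("chain does not fit the domain")
    return cfg


def make_small_sweep(
    seed: int,
    diameter: float = 50.0,
    vf_grid: tuple = DEFAULT_VF_GRID,
    n_realizations: int = 50,
    equil_cycles: int = 2000,
    thinning: int = 10,
) -> SweepConfig:
    """A frozen desk-scale sweep bundle; same seed => identical bundle.

    The returned SweepConfig is fully deterministic given its fields
    (its manifest() is the bundle manifest) and feeds
    :func:`mcfperc.sweep.run_sweep` directly.
    """
    return SweepConfig(
        diameter=diameter,
        vf_grid=tuple(float(v) for v in vf_grid),
        n_realizations=n_realizations,
        equil_cycles=equil_cycles,
        thinning=thinning,
        seed=int(seed),
    )
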