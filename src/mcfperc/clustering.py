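"""Connectivity graphs and cluster extraction.

Two platelets are connected either through their hydrated shells (the
minimum surface distance is at most the cut-off delta of long-range
electrostatic interactions, 14 angstrom) or by actual interpenetration
(crystals that coalesced into a continuum).  Connected components are
merged with the tree-based union-find at the core of the Newman-Ziff
cluster algorithm (path compression + union by size).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import kernels
from .configuration import Configuration

__all__ = [
    "ConnectivityCriterion",
    "ClusterSet",
    "UnionFind",
    "neighbor_candidates",
    "pair_table",
    "connected_pairs",
    "build_clusters",
]

#: Cut-off distance of long-range interactions between platelets via
#: their hydrated layers: 14 angstrom.
DEFAULT_DELTA_NM = 1.4


@dataclass(frozen=True)
class ConnectivityCriterion:
    """Which pairs of platelets count as connected.

    mode "shell": pairs with minimum distance d <= delta.  The literal
    shell relation is 0 < d <= delta; by default interpenetrating pairs
    (d = 0) are *also* connected (include_overlapping_in_shell=True),
    since a coalesced pair is a fortiori in contact - set it to False
    for the strict reading.
    mode "interpenetration": only pairs with positive overlap volume.
    """

    mode: str = "shell"
    delta: float = DEFAULT_DELTA_NM
    include_overlapping_in_shell: bool = True

    def __post_init__(self):
        if self.mode not in ("shell", "interpenetration"):
            raise ValueError(f"unknown connectivity mode {self.mode!r}")
        if self.mode == "shell" and self.delta <= 0:
            raise ValueError("delta must be positive in shell mode")

    @property
    def reach(self) -> float:
        """Exploring-volume reach for the neighbour search (nm)."""
        return self.delta if self.mode == "shell" else 0.0


class UnionFind:
    """Disjoint sets over 0..n-1 with path compression and union by size."""

    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.int64)
        self.size = np.ones(n, dtype=np.int64)

    def find(self, i: int) -> int:
        parent = self.parent
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return int(root)

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]


@dataclass
class ClusterSet:
    """A partition of platelet indices into connected components."""

    n_platelets: int
    labels: np.ndarray          # (n,) component label per platelet
    clusters: list[list[int]]   # member ids per component, largest first

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def neighbor_candidates(
    cfg: Configuration, reach: float
) -> list[tuple[int, int]]:
    """Candidate pairs from a uniform cell list (exploring volume).

    Cell edge >= max platelet diagonal + reach, so two platelets whose
    true minimum distance is <= reach always fall in the same or
    adjacent cells: the returned set is a guaranteed superset, each
    unordered pair listed once.
    """
    if reach < 0:
        raise ValueError("reach must be >= 0")
    n = cfg.n_platelets
    if n < 2:
        return []
    diag = 2.0 * np.linalg.norm(cfg.half_dims, axis=1).max()
    edge = diag + reach
    cells: dict[tuple[int, int, int], list[int]] = {}
    keys = np.floor(cfg.centroids / edge).astype(np.int64)
    for i in range(n):
        cells.setdefault(tuple(keys[i]), []).append(i)
    pairs: list[tuple[int, int]] = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    for (cx, cy, cz), members in cells.items():
        for dx, dy, dz in offsets:
            other = cells.get((cx + dx, cy + dy, cz + dz))
            if other is None:
                continue
            for i in members:
                for j in other:
                    if i < j:
                        pairs.append((i, j))
    return pairs


def pair_table(cfg: Configuration, reach: float):
    """(i, j, distance, overlap volume) for every pair within reach.

    The prescreen keeps pairs whose axis-aligned bounds are within reach
    on every axis (a superset of the true-distance criterion); exact
    distances come from the convex minimum-distance solver and overlap
    volumes from the clipping kernel.
    """
    return kernels.pair_table_kernel(
        cfg.centroids, cfg.orientations, cfg.half_dims, cfg.aabbs(), reach
    )


def connected_pairs(
    cfg: Configuration, crit: ConnectivityCriterion
) -> list[tuple[int, int]]:
    """Edge list of the connectivity graph under a criterion."""
    ii, jj, dd, vv = pair_table(cfg, crit.reach)
    edges: list[tuple[int, int]] = []
    for i, j, d, v in zip(ii, jj, dd, vv):
        if crit.mode == "interpenetration":
            keep = v > 0.0
        else:
            if d > crit.delta:
                keep = False
            elif d > 0.0:
                keep = True
            else:
                # d == 0: touching or interpenetrating
                keep = crit.include_overlapping_in_shell or v == 0.0
        if keep:
            edges.append((int(i), int(j)))
    return edges


def build_clusters(
    n: int, edges: Iterable[Sequence[int]]
) -> ClusterSet:
    """Union-find over n platelets; components match graph traversal."""
    uf = UnionFind(n)
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"edge endpoint out of range: ({i}, {j})")
        uf.union(int(i), int(j))
    roots = np.array([uf.find(i) for i in range(n)], dtype=np.int64)
    labels = np.empty(n, dtype=np.int64)
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(roots):
        groups.setdefault(int(r), []).append(i)
    clusters = sorted(groups.values(), key=len, reverse=True)
    for lab, members in enumerate(clusters):
        for i in members:
            labels[i] = lab
    return ClusterSet(n, labels, clusters)
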