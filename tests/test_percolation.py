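"""Spanning tests, percolation probabilities and the tanh transition fit."""

import numpy as np
import pytest

from mcfperc.clustering import build_clusters
from mcfperc.configuration import Configuration
from mcfperc.fixtures import make_chain_scene
from mcfperc.geometry import FibrilDomain, Platelet, platelet_vertices
from mcfperc.percolation import (
    PercolationCurve,
    SpanningThresholds,
    cluster_extent,
    fit_curve,
    is_percolating,
    passes_ring_filter,
    percolation_probability,
    tanh_curve,
)

from oracles import random_platelet

GRID = np.round(np.arange(0.07, 0.521, 0.05), 2)


class TestClusterExtent:
    def test_single_unit_cube(self, domain50, cube):
        cfg = Configuration.from_platelets(
            domain50, [cube(0, center=(0, 0, 500))]
        )
        for axis in "WTL":
            lo, hi, ext = cluster_extent(cfg, [0], axis)
            assert ext == pytest.approx(1.0)

    def test_two_cubes_ten_apart_along_w(self, domain50, cube):
        cfg = Configuration.from_platelets(
            domain50,
            [cube(0, center=(-5, 0, 500)), cube(1, center=(5, 0, 500))],
        )
        assert cluster_extent(cfg, [0, 1], "W")[2] == pytest.approx(11.0)

    def test_matches_brute_force_vertex_scan(self, rng, domain50):
        platelets = [
            Platelet(
                k,
                random_platelet(rng, k, center_scale=5.0).centroid
                + [0, 0, 500.0],
                random_platelet(rng, k).half_dims,
                random_platelet(rng, k).orientation,
            )
            for k in range(8)
        ]
        cfg = Configuration.from_platelets(domain50, platelets)
        ids = [0, 2, 5, 7]
        all_verts = np.vstack([platelet_vertices(cfg.platelet(i)) for i in ids])
        for axis, col in (("W", 0), ("T", 1), ("L", 2)):
            lo, hi, ext = cluster_extent(cfg, ids, axis)
            assert lo == pytest.approx(all_verts[:, col].min())
            assert hi == pytest.approx(all_verts[:, col].max())


class TestRingFilter:
    thresholds = SpanningThresholds()

    def test_core_confined_cluster_fails(self, domain50, cube):
        cfg = Configuration.from_platelets(
            domain50, [cube(0, center=(0, 0, 500), half=1.0)]
        )
        assert not passes_ring_filter(cfg, [0], self.thresholds)

    def test_vertex_at_95_percent_radius_passes(self, domain50):
        p = Platelet(0, [0.95 * 25.0 - 0.5, 0, 500], [0.5, 1e-3, 0.5])
        cfg = Configuration.from_platelets(domain50, [p])
        assert passes_ring_filter(cfg, [0], self.thresholds)

    def test_vertex_exactly_at_ring_is_excluded(self, domain50):
        # strict inequality: a vertex exactly on the 90% circle fails
        p = Platelet(0, [0.9 * 25.0 - 0.5, 0, 500], [0.5, 1e-9, 0.5])
        cfg = Configuration.from_platelets(domain50, [p])
        assert not passes_ring_filter(cfg, [0], self.thresholds)


class TestIsPercolating:
    def test_w_spanning_chain_of_six(self, domain50):
        # six overlapping boxes along W, extent 50.6 nm >= the 50 nm
        # chord, reaching past 0.9 R on both sides
        cfg = make_chain_scene(
            "W", 6, -0.2, domain50, box_dims=(8.6, 4.0, 4.0)
        )
        thr = SpanningThresholds.for_domain(domain50)
        cluster = list(range(6))
        assert cluster_extent(cfg, cluster, "W")[2] == pytest.approx(50.6)
        assert is_percolating(cfg, cluster, "W", thr)

    def test_short_t_chain_does_not_span(self, domain50):
        cfg = make_chain_scene(
            "T", 5, 0.0, domain50, box_dims=(4.0, 4.0, 4.0)
        )
        thr = SpanningThresholds.for_domain(domain50)
        assert cluster_extent(cfg, list(range(5)), "T")[2] == 20.0
        assert not is_percolating(cfg, list(range(5)), "T", thr)

    def test_single_long_platelet_fails_reduced_length(self, domain50):
        p = Platelet(0, [0, 0, 500], [22.5, 1.75, 85.0])
        cfg = Configuration.from_platelets(domain50, [p])
        thr = SpanningThresholds.for_domain(domain50)
        thr = type(thr)(
            thr.w_percolation, thr.t_percolation, thr.l_cluster,
            min_cluster_size=1,
        )
        assert not is_percolating(cfg, [0], "L", thr)

    def test_small_clusters_excluded_from_spanning(self, domain50):
        cfg = make_chain_scene(
            "W", 4, -0.2, domain50, box_dims=(13.0, 4.0, 4.0)
        )
        thr = SpanningThresholds.for_domain(domain50)
        cluster = list(range(4))
        # extent passes the chord but the cluster is below 5 platelets
        assert cluster_extent(cfg, cluster, "W")[2] >= thr.w_percolation
        assert not is_percolating(cfg, cluster, "W", thr)

    def test_full_length_mode_requires_entire_length(self, domain50):
        thr = SpanningThresholds.for_domain(domain50, full_length_mode=True)
        thr = type(thr)(
            thr.w_percolation, thr.t_percolation, thr.l_cluster,
            full_length_mode=True, min_cluster_size=1,
        )
        # spans [−10, 1010]: in both caps and extent >= 1000
        a = Platelet(0, [0, 0, 10.0], [5, 2, 20.0])
        b = Platelet(1, [0, 0, 985.0], [5, 2, 26.0])
        cfg = Configuration.from_platelets(domain50, [a, b])
        assert is_percolating(cfg, [0, 1], "L", thr)
        # extent 960: touches both caps but does not span the length
        c = Platelet(0, [0, 0, 30.0], [5, 2, 10.0])
        d = Platelet(1, [0, 0, 970.0], [5, 2, 10.0])
        cfg2 = Configuration.from_platelets(domain50, [c, d])
        assert not is_percolating(cfg2, [0, 1], "L", thr)

    def test_unknown_direction_raises(self, domain50, cube):
        cfg = Configuration.from_platelets(
            domain50, [cube(0, center=(0, 0, 500))]
        )
        with pytest.raises(ValueError):
            is_percolating(cfg, [0], "X", SpanningThresholds())


class TestPercolationProbability:
    @pytest.mark.parametrize(
        "outcomes, expected",
        [([False] * 4, 0.0), ([True] * 5 + [False] * 5, 0.5), ([True] * 3, 1.0)],
    )
    def test_fraction(self, outcomes, expected):
        p, se = percolation_probability(outcomes)
        assert p == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percolation_probability([])


class TestFitCurve:
    def test_noiseless_recovery(self):
        P = tanh_curve(GRID, 0.35, 0.03)
        fit = fit_curve(GRID, P)
        assert fit.status == "ok"
        assert fit.vf_c == pytest.approx(0.35, abs=1e-6)
        assert fit.delta == pytest.approx(0.03, abs=1e-6)

    def test_curve_at_critical_vf_is_half(self):
        P = tanh_curve(GRID, 0.31, 0.05)
        fit = fit_curve(GRID, P)
        assert float(fit.evaluate(fit.vf_c)) == pytest.approx(0.5, abs=1e-12)

    def test_noisy_recovery_median_error(self):
        # binomial noise at N = 100 per grid point, 500 repetitions
        rng = np.random.default_rng(4)
        truth = tanh_curve(GRID, 0.35, 0.03)
        errs = []
        for _ in range(500):
            P = rng.binomial(100, truth) / 100.0
            fit = fit_curve(GRID, P, n_realizations=100)
            if fit.vf_c is not None:
                errs.append(abs(fit.vf_c - 0.35))
        assert np.median(errs) <= 0.01

    def test_all_zero_or_one_refused(self):
        assert fit_curve(GRID, np.zeros_like(GRID)).status == "no_transition"
        assert fit_curve(GRID, np.ones_like(GRID)).status == "no_transition"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_curve([0.1, 0.2], [0.0, 1.0])

    def test_empirical_crossing_reported(self):
        P = tanh_curve(GRID, 0.30, 0.02)
        fit = fit_curve(GRID, P)
        assert fit.vf_c_empirical == pytest.approx(0.32)


class TestPercolationCurve:
    def test_probabilities_and_errors(self):
        curve = PercolationCurve(GRID, np.arange(10), np.full(10, 50))
        assert np.allclose(curve.P, np.arange(10) / 50.0)
        assert curve.se[0] == 0.0

    def test_rejects_counts_above_n(self):
        with pytest.raises(ValueError):
            PercolationCurve([0.1, 0.2, 0.3], [5, 1, 1], [4, 4, 4])


def test_machinery_recovers_2d_site_percolation_threshold(rng):
    """Union-find + spanning + tanh fit applied to square-lattice site
    percolation recover the known threshold ~0.593 within finite-size
    error (internal sanity oracle for the cluster/fit stack)."""
    L = 32
    p_grid = np.arange(0.45, 0.76, 0.03)
    n_rep = 40
    n_span = []
    for p in p_grid:
        hits = 0
        for _ in range(n_rep):
            occ = rng.random((L, L)) < p
            idx = -np.ones((L, L), dtype=int)
            ids = np.argwhere(occ)
            for k, (i, j) in enumerate(ids):
                idx[i, j] = k
            edges = []
            for k, (i, j) in enumerate(ids):
                if i + 1 < L and occ[i + 1, j]:
                    edges.append((k, idx[i + 1, j]))
                if j + 1 < L and occ[i, j + 1]:
                    edges.append((k, idx[i, j + 1]))
            cs = build_clusters(len(ids), edges)
            top = set(idx[0, occ[0]])
            bottom = set(idx[L - 1, occ[L - 1]])
            for cluster in cs.clusters:
                s = set(cluster)
                if s & top and s & bottom:
                    hits += 1
                    break
        n_span.append(hits)
    curve = PercolationCurve(p_grid, np.array(n_span), np.full(len(p_grid), n_rep))
    fit = fit_curve(curve.vf_grid, curve.P, n_realizations=curve.N)
    assert fit.status == "ok"
    assert abs(fit.vf_c - 0.5927) < 0.05
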