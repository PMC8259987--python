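"""Subcellular-element mechanics: lattice construction, force terms,
sorting behaviour and tissue integrity."""

import numpy as np
import pytest

from rhombosim.geometry import DomainState, Geometry
from rhombosim.mechanics import (
    CellCollection,
    MechanicsParams,
    NODES_PER_CELL,
    _hex_template,
    external_velocity,
    init_lattice,
    inter_velocity,
    intra_velocity,
    similarity_weight,
    step_mechanics,
)

P = MechanicsParams()


def make_cells(centers, params=P):
    t = _hex_template(params)
    nodes = np.vstack([t + np.asarray(c) for c in centers])
    return CellCollection(nodes, params)


class TestLattice:
    def test_cell_count_is_345(self, geometry):
        cells = init_lattice(geometry.state(11.0))
        assert cells.n_cells == 345

    def test_centroids_inside_tissue_domain(self, geometry):
        st = geometry.state(11.0)
        cen = init_lattice(st).centroids
        assert np.all(cen[:, 0] >= st.tissue_x_min)
        assert np.all(cen[:, 0] <= st.tissue_x_max)
        assert np.all(np.abs(cen[:, 1]) <= st.L2 / 2)

    def test_ap_spacing_matches_extent_over_rows(self, geometry):
        st = geometry.state(11.0)
        cen = init_lattice(st).centroids
        xs = np.unique(np.round(cen[:, 0], 6))
        assert len(xs) == 23
        spacing = np.diff(xs).mean()
        assert spacing == pytest.approx(st.tissue_extent / 23, rel=1e-6)


class TestIntraForces:
    def test_rest_configuration_has_zero_velocity(self):
        v = intra_velocity(_hex_template(P), P)
        np.testing.assert_allclose(v, 0.0, atol=1e-9)

    def test_inflated_cell_relaxes_inward(self):
        nodes = 1.3 * _hex_template(P)
        v = intra_velocity(nodes, P)
        # radial component points inward for the outer ring
        radial = np.sum(v[:6] * nodes[:6], axis=1)
        assert np.all(radial < 0)

    def test_internal_forces_cancel(self, rng):
        nodes = _hex_template(P) + rng.normal(0, 0.5, (12, 2))
        v = intra_velocity(nodes, P)
        np.testing.assert_allclose(v.sum(axis=0), 0.0, atol=1e-10)


class TestSimilarity:
    def test_anchor_values(self):
        assert similarity_weight(3.0, 3.0) == pytest.approx(1.0, abs=1e-3)
        assert similarity_weight(0.0, 0.0) == pytest.approx(1.0, abs=1e-3)
        assert similarity_weight(3.0, 0.0) == pytest.approx(0.0, abs=1e-3)
        assert similarity_weight(1.2, 1.2) == pytest.approx(0.5, abs=1e-9)

    def test_symmetry(self, rng):
        a, b = rng.uniform(0, 3, 2)
        assert similarity_weight(a, b) == pytest.approx(similarity_weight(b, a))


class TestInterForces:
    def test_similar_cells_attract_at_long_range(self):
        t = _hex_template(P)
        va, vb = inter_velocity(t, t + [9.0, 0.0], F=1.0, params=P)
        # net motion of a toward b (positive x) and b toward a
        assert va.mean(axis=0)[0] > 0
        assert vb.mean(axis=0)[0] < 0

    def test_dissimilar_cells_do_not_approach(self):
        t = _hex_template(P)
        va, vb = inter_velocity(t, t + [9.0, 0.0], F=0.0, params=P)
        assert va.mean(axis=0)[0] <= 0
        assert vb.mean(axis=0)[0] >= 0

    def test_neutral_similarity_leaves_only_core_repulsion(self):
        t = _hex_template(P)
        va, _ = inter_velocity(t, t + [9.0, 0.0], F=0.5, params=P)
        # at 9 micron separation the core repulsion is tiny but >= 0
        assert va.mean(axis=0)[0] <= 1e-6

    def test_pairwise_antisymmetry(self, rng):
        t = _hex_template(P)
        va, vb = inter_velocity(t, t + [7.0, 2.0], F=0.8, params=P)
        np.testing.assert_allclose(va.sum(axis=0), -vb.sum(axis=0), atol=1e-10)


class TestExternalVelocity:
    def test_zero_at_origin_and_equal_on_all_nodes(self, geometry):
        st = geometry.state(11.5)
        v = external_velocity(_hex_template(P), st)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)
        v2 = external_velocity(_hex_template(P) + [50.0, 10.0], st)
        assert np.ptp(v2[:, 0]) == 0.0
        assert np.ptp(v2[:, 1]) == 0.0


class TestStepMechanics:
    def test_isolated_resting_cell_is_stationary(self):
        cells = make_cells([(0.0, 0.0)])
        before = cells.nodes.copy()
        step_mechanics(cells, None, 1e-2, np.array([0.0]))
        np.testing.assert_allclose(cells.nodes, before, atol=1e-12)

    def test_kernel_matches_reference_pair_forces(self):
        """Cross-validation: the numba kernel's inter-cell contribution
        equals the dense numpy reference on a two-cell system."""
        centers = [(0.0, 0.0), (7.5, 1.0)]
        cells = make_cells(centers)
        K = np.array([2.0, 0.0])
        dt = 1e-5
        before = cells.nodes.copy()
        step_mechanics(cells, None, dt, K)
        moved = (cells.nodes - before) / dt
        F = similarity_weight(2.0, 0.0, threshold=1.2, width=P.sim_steepness)
        va, vb = inter_velocity(before[:12], before[12:], F=F, params=P)
        ref = np.vstack([va + intra_velocity(before[:12], P),
                         vb + intra_velocity(before[12:], P)])
        np.testing.assert_allclose(moved, ref, rtol=1e-6, atol=1e-9)

    def test_momentum_bookkeeping(self, rng):
        centers = rng.uniform(0, 30, (12, 2))
        cells = make_cells(centers)
        K = rng.uniform(0, 3, 12)
        before = cells.nodes.copy()
        step_mechanics(cells, None, 1e-5, K)
        # intra + inter forces are pairwise antisymmetric: total momentum 0
        np.testing.assert_allclose(
            (cells.nodes - before).sum(axis=0), 0.0, atol=1e-9
        )

    def test_two_cell_sorting_toy_separates_dissimilar_overlap(self):
        cells = make_cells([(0.0, 0.0), (3.0, 0.0)])  # deeply overlapping
        K = np.array([2.5, 0.0])
        for _ in range(3000):
            step_mechanics(cells, None, 1e-3, K)
        cen = cells.centroids
        dist = np.hypot(*(cen[1] - cen[0]))
        assert dist >= 2 * P.R_out * 0.9

    def test_displacement_guard_rejects_large_dt(self):
        cells = make_cells([(0.0, 0.0), (0.5, 0.0)])  # extreme overlap
        with pytest.raises(ValueError):
            step_mechanics(cells, None, 5.0, np.array([0.0, 0.0]))


def two_stripe_toy(rng, spacing=8.0, n_misplaced=12):
    """60-cell two-identity stripe toy (10 A-P rows x 6 columns).

    Rows 0-4 carry the krox20-low identity, rows 5-9 krox20-high; 20%
    of the cells flip identity with probability decaying away from the
    interface, mimicking the graded salt-and-pepper misplacement of the
    Gaussian-mixture initial condition.
    """
    centers = [(row * spacing, col * spacing) for row in range(10) for col in range(6)]
    kl = np.array([0.0 if row < 5 else 2.5 for row in range(10) for _ in range(6)])
    interface = 4.5 * spacing
    n_flip = 0
    for i in rng.permutation(60):
        depth = abs(centers[i][0] - interface)
        if rng.random() < 0.9 * np.exp(-depth / 14.0) and n_flip < n_misplaced:
            kl[i] = 2.5 if kl[i] == 0.0 else 0.0
            n_flip += 1
    return centers, kl


class TestSortingEfficacy:
    def test_misplacement_penalty_decreases_in_two_stripe_toy(self):
        """With 20% of cells misplaced around the interface, selective
        sorting strictly decreases the total penetration penalty (the
        sharpness index) in expectation over one simulated hour."""
        from rhombosim.metrics import find_boundary

        drops = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            centers, kl = two_stripe_toy(rng)
            cells = make_cells(centers)

            def sharpness():
                cen = cells.centroids[:, 0]
                b = find_boundary(cen[kl == 0.0], cen[kl == 2.5],
                                  (cen.min(), cen.max()), P.R_out)
                return b.SI

            si0 = sharpness()
            for _ in range(1000):
                step_mechanics(cells, None, 1e-3, kl)
            drops.append(si0 - sharpness())
        assert np.mean(drops) > 0
        assert np.mean(np.asarray(drops) > 0) >= 0.8  # most seeds improve

    def test_neutral_similarity_does_not_sort(self):
        """With F pinned at 0.5 and no growth, the A-P rank order of
        identities is statistically unchanged (no systematic sorting)."""
        shifts = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            centers, kl = two_stripe_toy(rng)
            cells = make_cells(centers)
            rank0 = np.mean(np.argsort(np.argsort(cells.centroids[:, 0]))[kl > 1])
            for _ in range(1000):
                step_mechanics(cells, None, 1e-3, kl, neutral_similarity=True)
            rank1 = np.mean(np.argsort(np.argsort(cells.centroids[:, 0]))[kl > 1])
            shifts.append(rank1 - rank0)
        # mean rank shift stays within one rank position
        assert abs(np.mean(shifts)) < 1.0


class TestIntegrity:
    def test_radius_of_gyration_stays_bounded(self):
        """Cell shapes stay within +-25% of the rest radius of gyration
        through a crowded, sorting hour."""
        rng = np.random.default_rng(0)
        centers, kl = two_stripe_toy(rng, spacing=7.0)
        cells = make_cells(centers)
        rest_rg = CellCollection(_hex_template(P), P).radii_of_gyration()[0]
        for _ in range(1000):
            step_mechanics(cells, None, 1e-3, kl)
        rg = cells.radii_of_gyration()
        assert np.all(rg > 0.75 * rest_rg)
        assert np.all(rg < 1.25 * rest_rg)
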