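"""Morphogen fields: production/degradation terms, interpolation, the
equilibrium solver, and conservation/convergence properties of the
stochastic stepper."""

import numpy as np
import pytest

from rhombosim.geometry import DomainState, Geometry
from rhombosim.morphogens import (
    FGFParams,
    MorphogenGrid,
    RAParams,
    fgf_production_rate,
    interpolate_grid_to_points,
    interpolate_points_to_grid,
    ra_degradation_rate,
    ra_production_rate,
    solve_ra_steady_state,
    stable_dt,
    step_morphogens,
)


def static_state(L1=300.0, L2=104.0, p=230.0, **kw):
    return DomainState(t=14.0, L1=L1, L2=L2, p=p, dL1dt=0.0, dL2dt=0.0, **kw)


class TestReactionTerms:
    def test_ra_production_hill_midpoint(self):
        assert ra_production_rate(230.0, 230.0, 2.0) == pytest.approx(1.0)

    def test_ra_production_vanishes_anteriorly(self):
        assert ra_production_rate(0.0, 230.0, 2.0) == 0.0
        assert ra_production_rate(1e-9, 230.0, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_ra_production_direct_value(self):
        # x = 1.2 p: 1/(1 + 1.2^-20)
        expected = 1.0 / (1.0 + 1.2 ** (-20))
        assert ra_production_rate(1.2 * 230.0, 230.0, 1.0) == pytest.approx(
            expected, rel=1e-9
        )
        assert expected == pytest.approx(0.9744, abs=2e-4)

    def test_ra_degradation_piecewise_strict(self):
        p, kmax, k0 = 230.0, 8.0, 1.0
        assert ra_degradation_rate(1.5 * p, p, kmax, k0) == kmax
        assert ra_degradation_rate(0.5 * p, p, kmax, k0) == k0
        assert ra_degradation_rate(p, p, kmax, k0) == k0  # strict inequality

    def test_fgf_production_limits(self):
        assert fgf_production_rate(0.0, 5.0, 0.2) == 0.0
        assert fgf_production_rate(1e6, 5.0, 0.2) == pytest.approx(25.0, rel=1e-6)
        assert fgf_production_rate(1.0, 1.0, 1.0) == pytest.approx(0.5)


class TestGridPointInterpolation:
    def test_constant_field(self, rng):
        st = static_state()
        grid = MorphogenGrid(16, 8)
        f = np.full((16, 8), 3.7)
        pts = np.stack(
            [rng.uniform(0, st.L1, 40), rng.uniform(-st.L2 / 2, st.L2 / 2, 40)], axis=1
        )
        np.testing.assert_allclose(interpolate_grid_to_points(f, pts, st), 3.7)

    def test_node_coincidence(self):
        st = static_state()
        grid = MorphogenGrid(16, 8)
        f = np.arange(16 * 8, dtype=float).reshape(16, 8)
        x1 = grid.x1(st)
        x2 = grid.x2(st)
        pts = np.array([[x1[3], x2[5]], [x1[10], x2[2]]])
        vals = interpolate_grid_to_points(f, pts, st)
        np.testing.assert_allclose(vals, [f[3, 5], f[10, 2]], rtol=1e-12)

    def test_bilinear_exact_on_linear_field(self, rng):
        st = static_state()
        grid = MorphogenGrid(12, 6)
        x1 = grid.x1(st)[:, None]
        x2 = grid.x2(st)[None, :]
        f = 0.02 * x1 + 0.05 * x2 + 1.0
        # interior points only (edges clamp)
        pts = np.stack(
            [rng.uniform(x1[1, 0], x1[-2, 0], 60),
             rng.uniform(x2[0, 1], x2[0, -2], 60)],
            axis=1,
        )
        vals = interpolate_grid_to_points(f, pts, st)
        np.testing.assert_allclose(vals, 0.02 * pts[:, 0] + 0.05 * pts[:, 1] + 1.0,
                                   rtol=1e-12)


class TestPointsToGrid:
    def test_constant_values_reproduced_over_tissue(self):
        st = static_state()
        grid = MorphogenGrid(64, 16)
        xs = np.linspace(40, 200, 23)
        ys = np.linspace(-45, 45, 15)
        pts = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
        field = interpolate_points_to_grid(pts, np.full(len(pts), 2.5), grid, st)
        x1 = grid.x1(st)
        inside = (x1 > 60) & (x1 < 180)
        mid_j = grid.ny // 2
        np.testing.assert_allclose(field[inside, mid_j], 2.5, rtol=1e-9)

    def test_zero_far_from_any_cell(self):
        st = static_state()
        grid = MorphogenGrid(64, 16)
        pts = np.array([[100.0, 0.0]])
        field = interpolate_points_to_grid(pts, np.array([4.0]), grid, st)
        x1 = grid.x1(st)
        assert np.all(field[x1 > 150, :] == 0.0)
        assert np.all(field[x1 < 50, :] == 0.0)

    def test_stripe_maximum_inside_stripe(self):
        st = static_state()
        grid = MorphogenGrid(64, 16)
        xs = np.linspace(40, 200, 40)
        pts = np.stack([xs, np.zeros_like(xs)], axis=1)
        vals = np.where((xs > 110) & (xs < 150), 3.0, 0.1)
        field = interpolate_points_to_grid(pts, vals, grid, st, rx=9, ry=22)
        x1 = grid.x1(st)
        peak = x1[np.argmax(field[:, grid.ny // 2])]
        assert 110 < peak < 150

    def test_no_cells_gives_zero_field(self):
        st = static_state()
        grid = MorphogenGrid(16, 8)
        field = interpolate_points_to_grid(np.empty((0, 2)), np.empty(0), grid, st)
        assert np.all(field == 0.0)


class TestSteadyState:
    def test_zero_production_zero_fields(self):
        grid = solve_ra_steady_state((32, 8), static_state(), RAParams(vr=0.0))
        np.testing.assert_allclose(grid.RAout, 0.0, atol=1e-12)
        np.testing.assert_allclose(grid.RAin, 0.0, atol=1e-12)

    def test_lr_symmetry(self):
        grid = solve_ra_steady_state((32, 8), static_state(), RAParams())
        np.testing.assert_allclose(grid.RAout, grid.RAout[:, ::-1], rtol=1e-9)

    def test_monotone_decrease_toward_anterior(self):
        grid = solve_ra_steady_state((64, 8), static_state(), RAParams())
        mid = grid.RAout[:, 4]
        # outside the production region the profile decays anteriorly
        x1 = grid.x1(static_state())
        sel = x1 < 220.0
        assert np.all(np.diff(mid[sel]) > 0)

    def test_well_mixed_fixed_point_closed_form(self):
        """Uniform production, huge diffusion, no absorbing boundary:
        the fields reach the analytic two-variable fixed point
        RAin* = kr RAout*/(kr+dr), RAout* = a/(kr((1+br) - kr/(kr+dr)))."""
        a, kr, br, k0 = 2.0, 1.5, 0.8, 0.7
        # p tiny: production ~ a everywhere; but keep x < p ... dr = k0
        st = DomainState(t=14.0, L1=100.0, L2=50.0, p=99.9999, dL1dt=0.0, dL2dt=0.0)
        rp = RAParams(Dr=500.0, vr=a, kr=kr, beta_r=br, kmax=k0, k0=k0,
                      mu_r1=0, mu_r2=0)
        fp = FGFParams(Df=500.0, mu_f1=0, mu_f2=0)
        # production region covers x > p: shrink p to zero via a custom state
        st = DomainState(t=14.0, L1=100.0, L2=50.0, p=1e-6, dL1dt=0.0, dL2dt=0.0)
        grid = MorphogenGrid(8, 4)
        dx, dy = st.L1 / 8, st.L2 / 4
        dt = 0.4 / (2 * rp.Dr * (1 / dx**2 + 1 / dy**2))
        rng = np.random.default_rng(0)
        for _ in range(int(30.0 / dt)):
            step_morphogens(grid, st, dt, rng, rp, fp, ra_absorbing_left=False)
        ra_in_star = kr / (kr + k0)  # per unit RAout
        ra_out_star = a / (kr * ((1 + br) - kr / (kr + k0)))
        np.testing.assert_allclose(grid.RAout, ra_out_star, rtol=1e-3)
        np.testing.assert_allclose(grid.RAin, ra_in_star * ra_out_star, rtol=1e-3)

    def test_long_time_stepping_matches_steady_solver(self):
        """Self-consistency: zero-noise stepping on a static domain
        converges to the sparse-solver equilibrium."""
        st = static_state()
        rp = RAParams(mu_r1=0, mu_r2=0)
        fp = FGFParams(mu_f1=0, mu_f2=0)
        ref = solve_ra_steady_state((32, 8), st, rp)
        grid = MorphogenGrid(32, 8)
        dt = stable_dt(Geometry.default(), rp, fp, (32, 8))
        rng = np.random.default_rng(0)
        for _ in range(int(12.0 / dt)):
            step_morphogens(grid, st, dt, rng, rp, fp)
        np.testing.assert_allclose(grid.RAout, ref.RAout, rtol=2e-2, atol=1e-3)
        np.testing.assert_allclose(grid.RAin, ref.RAin, rtol=2e-2, atol=1e-3)


class TestOneDAnalytic:
    def test_absorbing_profile_matches_sinh_solution(self):
        """Outside the production region the deterministic RAout profile
        solves D C'' = k_eff C with C(0) = 0, i.e. C = A sinh(x/lam).
        Fit A at one point and compare everywhere else."""
        st = static_state()
        rp = RAParams()
        grid = solve_ra_steady_state((128, 4), st, rp)
        x = grid.x1(st)
        mid = grid.RAout[:, 2]
        k_eff = (1 + rp.beta_r) * rp.kr - rp.kr**2 / (rp.kr + rp.k0)
        lam = np.sqrt(rp.Dr / k_eff)
        sel = (x > 5.0) & (x < 180.0)  # far from the production region
        A = mid[sel][0] / np.sinh(x[sel][0] / lam)
        np.testing.assert_allclose(mid[sel], A * np.sinh(x[sel] / lam), rtol=2e-2)


class TestStepper:
    def test_cfl_violation_rejected(self):
        st = static_state()
        grid = MorphogenGrid(32, 8)
        with pytest.raises(ValueError):
            step_morphogens(grid, st, 1.0, np.random.default_rng(0),
                            RAParams(), FGFParams())

    def test_mass_conserved_without_reactions_on_moving_domain(self):
        """No production, no exchange, no degradation, no-flux boundaries:
        the integral of the field over the deforming domain is constant."""
        geom = Geometry.default("rapid")
        rng = np.random.default_rng(1)
        grid = MorphogenGrid(32, 16)
        xi = grid.xi[:, None]
        eta = grid.eta[None, :]
        grid.RAout = 1.0 + 0.5 * np.sin(2 * np.pi * xi) * np.cos(np.pi * eta)
        rp = RAParams(Dr=2500.0, vr=0.0, kr=0.0, beta_r=0.0, kmax=0.0, k0=0.0,
                      mu_r1=0, mu_r2=0)
        fp = FGFParams(vf=0.0, kf=0, krf=0, df1=0, df2=0, mu_f1=0, mu_f2=0)
        dt = stable_dt(geom, rp, fp, (32, 16))
        st0 = geom.state(11.0)
        mass0 = st0.L1 * st0.L2 * grid.RAout.mean()
        t = 11.0
        while t < 12.0:
            st = geom.state(min(t + dt / 2, 14.0))  # midpoint geometry
            step_morphogens(grid, st, dt, rng, rp, fp, ra_absorbing_left=False)
            t += dt
        st1 = geom.state(t)
        mass1 = st1.L1 * st1.L2 * grid.RAout.mean()
        # explicit Euler treats the dilution factor to first order in dt,
        # so conservation holds to O(dt); the drift halves with dt
        assert mass1 == pytest.approx(mass0, rel=5e-4)

    def test_fields_non_negative_with_noise(self):
        st = static_state()
        grid = MorphogenGrid(16, 8)
        rp = RAParams(mu_r1=3.0, mu_r2=3.0)
        fp = FGFParams(mu_f1=3.0, mu_f2=3.0)
        rng = np.random.default_rng(2)
        dt = 1e-4
        for _ in range(200):
            step_morphogens(grid, st, dt, rng, rp, fp)
        for f in (grid.RAout, grid.RAin, grid.FGFfree, grid.FGFsignal):
            assert np.all(f >= 0.0)

    def test_zero_noise_static_domain_is_deterministic_update(self):
        st = static_state()
        rp = RAParams(mu_r1=0, mu_r2=0)
        fp = FGFParams(mu_f1=0, mu_f2=0)
        g1 = MorphogenGrid(16, 8)
        g1.RAout += 1.0
        g2 = g1.copy()
        step_morphogens(g1, st, 1e-4, np.random.default_rng(0), rp, fp)
        step_morphogens(g2, st, 1e-4, np.random.default_rng(99), rp, fp)
        np.testing.assert_array_equal(g1.RAout, g2.RAout)

    def test_ensemble_mean_approaches_deterministic_with_small_noise(self):
        """Weak-convergence sanity: the ensemble-mean deviation from the
        deterministic solution shrinks with the noise amplitude."""
        st = static_state()
        fp = FGFParams(mu_f1=0, mu_f2=0)
        det = MorphogenGrid(16, 4)
        rp0 = RAParams(mu_r1=0, mu_r2=0)
        dt = 5e-5
        for _ in range(400):
            step_morphogens(det, st, dt, np.random.default_rng(0), rp0, fp)
        devs = []
        for mu in (0.2, 0.8, 3.2):
            mean = np.zeros_like(det.RAout)
            n_rep = 8
            for rep in range(n_rep):
                g = MorphogenGrid(16, 4)
                rng = np.random.default_rng(100 + rep)
                rp = RAParams(mu_r1=mu, mu_r2=mu)
                for _ in range(400):
                    step_morphogens(g, st, dt, rng, rp, fp)
                mean += g.RAout / n_rep
            devs.append(np.linalg.norm(mean - det.RAout))
        assert devs[0] < devs[1] < devs[2]

    def test_grid_refinement_convergence(self):
        """Halving the grid spacing changes the deterministic 14 hpf RA
        fields by < 2% in relative L2 norm."""
        st = static_state()
        rp = RAParams()
        coarse = solve_ra_steady_state((64, 16), st, rp)
        fine = solve_ra_steady_state((128, 32), st, rp)
        f_on_c = 0.5 * (fine.RAout[0::2, 0::2] + fine.RAout[1::2, 1::2])
        rel = np.linalg.norm(coarse.RAout - f_on_c) / np.linalg.norm(f_on_c)
        assert rel < 0.02
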