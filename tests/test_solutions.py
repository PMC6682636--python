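"""Bump existence/stability and 1D traveling-wave solutions."""

import numpy as np
import pytest
from scipy.linalg import expm

from nfwaves import (
    KernelParams,
    ModelParams,
    Wave1D,
    bump_existence_residual,
    bump_profile,
    solve_bump_radii,
    solve_wave1d,
    wave1d_profile,
)
from nfwaves.solutions import (
    _boundary_residuals,
    bump_boundary_input,
    disc_input,
    line_kernel,
)


class TestBumpProfile:
    def test_interior_values(self, model):
        b = bump_profile(3.0, model)
        assert b.f_in == pytest.approx(0.42 / 1.84)
        assert b.h_in == pytest.approx(1.0 / 1.84)

    def test_interior_identity_exact(self):
        for p in (0.1, 0.42, 1.7, 3.9):
            m = ModelParams(p=p)
            assert m.f_in + m.h_in == pytest.approx((1 + p) / (1 + 2 * p), rel=1e-14)

    def test_interior_is_fixed_point(self, model):
        # with the Heaviside active: -f + (1 - f - h) = 0 and -p h + f = 0
        f, h = model.f_in, model.h_in
        assert -f + (1 - f - h) == pytest.approx(0.0, abs=1e-15)
        assert -model.p * h + f == pytest.approx(0.0, abs=1e-15)

    def test_invalid_radius(self, model):
        with pytest.raises(ValueError):
            bump_profile(-1.0, model)


class TestDiscInput:
    def test_against_quadrature_oracle(self, fig_kernel):
        # brute-force 2D quadrature of the kernel over the disc
        from scipy.integrate import dblquad

        from nfwaves.kernel import eval_kernel

        rho = 2.0
        for r_eval in (rho, 0.5 * rho):
            def integrand(rp, th):
                d = np.sqrt(r_eval ** 2 + rp ** 2 - 2 * r_eval * rp * np.cos(th))
                return rp * float(eval_kernel(max(d, 1e-12), fig_kernel))

            oracle, _ = dblquad(integrand, 0, 2 * np.pi, 0, rho,
                                epsabs=1e-9, epsrel=1e-9)
            assert disc_input(rho, r_eval, fig_kernel) == pytest.approx(
                oracle, rel=1e-6
            )


class TestBumpExistence:
    def test_residual_at_vanishing_radius(self, fig_kernel, model):
        # rho -> 0: the disc integral vanishes, leaving -kappa(1 + 4p)/(1 + 2p)
        expected = -model.kappa * (1 + 4 * model.p) / (1 + 2 * model.p)
        assert bump_existence_residual(1e-9, fig_kernel, model) == pytest.approx(
            expected, abs=1e-6
        )

    def test_residual_zero_at_solutions(self, fig_kernel, model):
        sols = solve_bump_radii(fig_kernel, model)
        assert len(sols) == 2
        for s in sols:
            assert abs(bump_existence_residual(s.rho, fig_kernel, model)) < 1e-8

    def test_at_most_two_solutions(self, fig_kernel, model):
        assert len(solve_bump_radii(fig_kernel, model)) <= 2

    def test_boundary_input_unimodal(self, model):
        # u(rho) is unimodal: it rises to a single maximum and never rises
        # again (so the threshold line crosses it at most twice); kernels with
        # negligible inhibition may put that maximum beyond any finite radius
        from nfwaves.kernel import sample_kernels_mc

        for params, _ in sample_kernels_mc(3, seed=21):
            rhos = np.linspace(0.05 * params.sigma_E, 10 * params.sigma_I, 120)
            u = np.array([bump_boundary_input(r, params, model) for r in rhos])
            k = int(np.argmax(u))
            assert np.all(np.diff(u[: k + 1]) > -1e-9 * np.abs(u).max())
            assert np.all(np.diff(u[k:]) < 1e-9 * np.abs(u).max())

    def test_boundary_input_interior_max_reference(self, fig_kernel, model):
        rhos = np.linspace(0.1, 10 * fig_kernel.sigma_I, 200)
        u = np.array([bump_boundary_input(r, fig_kernel, model) for r in rhos])
        k = int(np.argmax(u))
        assert 0 < k < len(u) - 1

    def test_larger_branch_grows_with_excitation(self, model):
        radii = []
        for we in (144.4, 170.0, 200.0):
            sols = solve_bump_radii(KernelParams(we, 73.7, 1.87, 3.24), model)
            radii.append(max(s.rho for s in sols))
        assert radii[0] < radii[1] < radii[2]

    def test_large_threshold_kills_solutions(self, fig_kernel):
        model = ModelParams(p=0.42, kappa=50.0)
        assert solve_bump_radii(fig_kernel, model) == []


@pytest.fixture(scope="module")
def bump_branches(fig_kernel, model):
    sols = solve_bump_radii(fig_kernel, model)
    assert len(sols) == 2
    return sols


class TestBumpStabilityInSimulation:
    """Direct simulation confirms the branch-stability picture: radial
    perturbations of the larger bump relax back, the smaller bump collapses."""

    def _final_area(self, rho, fig_kernel, model):
        from nfwaves import NoiseSpec, SimConfig, make_initial, simulate

        cfg = SimConfig(grid_n=128, spacing=0.5, dt=0.01, duration=5.0,
                        snapshot_stride=100, kernel=fig_kernel, model=model,
                        noise=NoiseSpec())
        state = make_initial("bump", cfg, rho=rho)
        movie, _ = simulate(state, cfg)
        return (movie.frames[-1] > 0.5 * model.f_in).sum() * cfg.spacing ** 2

    def test_larger_branch_returns(self, bump_branches, fig_kernel, model):
        big = max(s.rho for s in bump_branches)
        area_eq = np.pi * big ** 2
        area = self._final_area(1.1 * big, fig_kernel, model)
        assert area == pytest.approx(area_eq, rel=0.15)

    def test_smaller_branch_departs(self, bump_branches, fig_kernel, model):
        small = min(s.rho for s in bump_branches)
        area_eq = np.pi * small ** 2
        area = self._final_area(0.8 * small, fig_kernel, model)
        # an under-sized unstable bump collapses to nothing
        assert area < 0.25 * area_eq


class TestShiftGrowthRate:
    def test_bump_is_drift_unstable_at_reference_p(self, fig_kernel, model):
        # at p = 0.42 the stable-radius bump is unstable to shift
        # perturbations: a sub-grid displacement grows exponentially
        from nfwaves.solutions import shift_growth_rate

        bump = max(solve_bump_radii(fig_kernel, model), key=lambda s: s.rho)
        res = shift_growth_rate(bump, fig_kernel, model, grid_n=128,
                                spacing=0.25, horizon=30.0)
        assert res.distinguishable
        assert res.rate > 0

    def test_displacement_series_recorded(self, fig_kernel, model):
        from nfwaves.solutions import shift_growth_rate

        bump = max(solve_bump_radii(fig_kernel, model), key=lambda s: s.rho)
        res = shift_growth_rate(bump, fig_kernel, model, grid_n=96,
                                spacing=0.25, horizon=5.0)
        assert len(res.times) == len(res.displacements)
        assert np.all(res.displacements >= 0)


class TestWave1DProfile:
    def test_front_boundary_values(self, model):
        w = Wave1D.from_cl(2.0, 5.0, model)
        F, H = wave1d_profile(0.0, w, model)
        assert F[0] == pytest.approx(0.0, abs=1e-14)
        assert H[0] == pytest.approx(0.0, abs=1e-14)

    def test_continuity_at_tail_junction(self, model):
        w = Wave1D.from_cl(1.5, 4.0, model)
        eps = 1e-9
        Fm, Hm = wave1d_profile(-w.L + eps, w, model)
        Fp, Hp = wave1d_profile(-w.L - eps, w, model)
        assert Fm[0] == pytest.approx(Fp[0], abs=1e-6)
        assert Hm[0] == pytest.approx(Hp[0], abs=1e-6)

    def test_matches_comoving_ode(self, model):
        # exact solution of dF/dx=(2F+H-1)/c, dH/dx=(pH-F)/c with F(0)=H(0)=0,
        # integrated by matrix exponential about the interior fixed point
        p, c = model.p, 3.0
        w = Wave1D.from_cl(c, 50.0, model)
        M = np.array([[2.0, 1.0], [-1.0, p]])
        d0 = np.array([-model.f_in, -model.h_in])
        for x in (-0.5, -2.0, -7.0):
            d = expm(M * x / c) @ d0
            F, H = wave1d_profile(x, w, model)
            assert F[0] == pytest.approx(model.f_in + d[0], abs=1e-12)
            assert H[0] == pytest.approx(model.h_in + d[1], abs=1e-12)

    def test_interior_approaches_fixed_point(self, model):
        w = Wave1D.from_cl(0.5, 40.0, model)
        F, _ = wave1d_profile(-w.L * 0.99, w, model)
        assert F[0] == pytest.approx(model.f_in, rel=0.05)

    def test_p_at_least_four_rejected(self):
        with pytest.raises(ValueError):
            Wave1D.from_cl(1.0, 1.0, ModelParams(p=4.0))


class TestSolveWave1D:
    def test_solution_satisfies_boundary_conditions(self, strong_kernel, model_p03):
        waves = solve_wave1d(strong_kernel, model_p03, seed=0)
        w = waves[-1]
        r0, rL = _boundary_residuals(w.c, w.L, strong_kernel, model_p03)
        assert abs(r0) < 1e-4 * model_p03.kappa
        assert abs(rL) < 1e-4 * model_p03.kappa

    def test_sorted_largest_last(self, fig_kernel, model_p03):
        waves = solve_wave1d(fig_kernel, model_p03, seed=0, n_starts=40)
        cl = [(w.c, w.L) for w in waves]
        assert cl == sorted(cl)

    def test_speed_and_length_grow_with_excitation(self, model_p03):
        slow = solve_wave1d(KernelParams(144.4, 73.7, 1.87, 3.24), model_p03, seed=0)[-1]
        fast = solve_wave1d(KernelParams(200.0, 73.7, 1.87, 3.24), model_p03, seed=0)[-1]
        assert fast.c > slow.c
        assert fast.L > slow.L

    def test_speed_length_positively_correlated_across_kernels(self, model_p03):
        # the (c, L) solutions line up on a positively correlated frontier
        cs, Ls = [], []
        for we in (144.4, 160.0, 180.0, 200.0, 220.0):
            try:
                w = solve_wave1d(
                    KernelParams(we, 73.7, 1.87, 3.24), model_p03, seed=0,
                    n_starts=12,
                )[-1]
            except Exception:
                continue
            cs.append(w.c)
            Ls.append(w.L)
        assert len(cs) >= 3
        r = np.corrcoef(cs, Ls)[0, 1]
        assert r > 0


class TestLineKernel:
    def test_even_and_decaying(self, fig_kernel):
        x = np.linspace(0.1, 40, 200)
        assert np.allclose(line_kernel(x, fig_kernel), line_kernel(-x, fig_kernel))
        assert abs(line_kernel(40.0, fig_kernel)) < 1e-3

    def test_transverse_integral_of_radial_kernel(self, fig_kernel):
        # line_kernel(x) must equal int w(sqrt(x^2+y^2)) dy
        from scipy.integrate import quad

        from nfwaves.kernel import eval_kernel

        for x in (0.5, 2.0, 5.0):
            oracle, _ = quad(
                lambda y: float(eval_kernel(np.hypot(x, y), fig_kernel)),
                -60, 60, limit=400,
            )
            assert line_kernel(x, fig_kernel) == pytest.approx(oracle, rel=1e-6)
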