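import numpy as np
import pytest

from foldcaustic import (
    VariationFunction,
    action_integral,
    build_chain,
    el_residual,
    find_conjugate_points,
    integrate_trajectory,
    jacobi_conjugate_points,
    second_variation_form,
)
from foldcaustic.dynamics import Trajectory
from foldcaustic.errors import NonStationaryTrajectoryError, ValidationError

from conftest import analytic_trajectory


class TestActionIntegral:
    def test_rest_in_zero_potential_gives_zero(self, free_chain):
        traj = integrate_trajectory(free_chain, 0.4, 0.0, 0.0, 2.0, 100)
        assert action_integral(free_chain, traj) == pytest.approx(0.0, abs=1e-14)

    def test_constant_lagrangian_exact(self):
        # V = -c constant: L = c at rest; Simpson is exact for constants
        c = 1.3
        chain = build_chain({"n_angles": 1, "inertias": 1.0,
                             "potential": {"kind": "custom",
                                           "expression": f"-{c} + 0*theta"}})
        traj = integrate_trajectory(chain, 0.0, 0.0, 0.5, 2.5, 64)
        assert action_integral(chain, traj) == pytest.approx(c * 2.0, rel=1e-12)

    def test_harmonic_quarter_arc_closed_form(self, harmonic_half_chain):
        # theta = sin t on [0, pi/4]: S = int (cos^2 - sin^2)/2 = sin(2t)/4 -> 1/4
        traj = analytic_trajectory(harmonic_half_chain, np.sin, np.cos,
                                   0.0, np.pi / 4, 512)
        assert action_integral(harmonic_half_chain, traj) == pytest.approx(
            0.25, rel=1e-8)

    def test_short_grid_rejected(self, free_chain):
        t = np.array([0.0, 1.0])
        traj = Trajectory(t=t, q=np.zeros((2, 1)), v=np.zeros((2, 1)),
                          chain=free_chain)
        with pytest.raises(ValidationError, match="Simpson"):
            action_integral(free_chain, traj)


class TestElResidual:
    def test_integrated_trajectory_small_residual(self, harmonic_half_chain):
        traj = integrate_trajectory(harmonic_half_chain, 1.0, 0.0, 0.0, 4.0, 400)
        assert el_residual(harmonic_half_chain, traj) < 1e-4

    def test_corrupted_trajectory_much_worse(self, harmonic_half_chain):
        traj = integrate_trajectory(harmonic_half_chain, 1.0, 0.0, 0.0, 4.0, 400)
        base = el_residual(harmonic_half_chain, traj)
        q = traj.q.copy()
        q[200, 0] += 0.1
        bad = Trajectory(t=traj.t, q=q, v=traj.v, chain=harmonic_half_chain)
        assert el_residual(harmonic_half_chain, bad) > 10 * max(base, 1e-12)

    def test_free_straight_line_exact(self, free_chain):
        t = np.linspace(0, 2, 101)
        q = (0.3 + 0.7 * t)[:, None]
        traj = Trajectory(t=t, q=q, v=np.full_like(q, 0.7), chain=free_chain)
        assert el_residual(free_chain, traj) < 1e-10  # round-off / h^2 scale

    def test_rk4_residual_second_order_in_h(self, harmonic_half_chain):
        # the residual operator is a second-order stencil
        res = [el_residual(harmonic_half_chain,
                           integrate_trajectory(harmonic_half_chain, 1.0, 0.0,
                                                0.0, 2.0, n, method="rk4"))
               for n in (100, 200, 400)]
        assert 3.0 < res[0] / res[1] < 5.0
        assert 3.0 < res[1] / res[2] < 5.0


class TestSecondVariationForm:
    def test_zero_potential_positive_definite(self, free_chain):
        traj = integrate_trajectory(free_chain, 0.0, 0.1, 0.0, 5.0, 200)
        form = second_variation_form(free_chain, traj)
        assert form.eigenvalues[0] > 0

    def test_harmonic_interval_shorter_than_pi_positive(self, harmonic_half_chain):
        traj = integrate_trajectory(harmonic_half_chain, 1.0, 0.0, 0.0, 3.0, 600)
        form = second_variation_form(harmonic_half_chain, traj)
        assert form.eigenvalues[0] > 0

    def test_harmonic_interval_past_pi_indefinite(self, harmonic_half_chain):
        traj = integrate_trajectory(harmonic_half_chain, 1.0, 0.0, 0.0, 3.3, 660)
        form = second_variation_form(harmonic_half_chain, traj)
        assert form.eigenvalues[0] < 0

    @pytest.mark.parametrize("T", [2.0, 3.0, 3.3])
    def test_sturm_liouville_eigenvalue_oracle(self, harmonic_half_chain, T):
        # smallest eigenvalue of -xidd - xi with Dirichlet ends: (pi/T)^2 - 1;
        # the FEM matrix eigenvalue approximates h * that value
        n = 800
        traj = integrate_trajectory(harmonic_half_chain, 1.0, 0.0, 0.0, T, n)
        form = second_variation_form(harmonic_half_chain, traj)
        lam = form.eigenvalues[0] / traj.h
        assert lam == pytest.approx((np.pi / T) ** 2 - 1.0, abs=2e-3)

    def test_sine_variation_value(self, free_chain):
        # m=1, V=0, xi = sin(pi t) on [0,1]: int pi^2 cos^2 = pi^2/2
        traj = integrate_trajectory(free_chain, 0.0, 0.0, 0.0, 1.0, 2000)
        form = second_variation_form(free_chain, traj)
        xi = np.sin(np.pi * traj.t)
        xi[0] = xi[-1] = 0.0
        assert form.form_value(xi) == pytest.approx(np.pi ** 2 / 2, rel=1e-4)

    def test_matrix_symmetric(self, harmonic_half_chain):
        traj = integrate_trajectory(harmonic_half_chain, 1.0, 0.0, 0.0, 2.0, 100)
        Q = second_variation_form(harmonic_half_chain, traj).matrix
        assert np.max(np.abs(Q - Q.T)) < 1e-12

    def test_form_value_matches_direct_quadrature(self, harmonic_half_chain):
        # invariant: xi^T Q xi equals trapezoid quadrature of the integrand
        # for the same piecewise-linear xi
        traj = integrate_trajectory(harmonic_half_chain, 0.5, 0.2, 0.0, 2.0, 300)
        form = second_variation_form(harmonic_half_chain, traj)
        rng = np.random.default_rng(7)
        xi = rng.standard_normal(traj.t.size)
        xi[0] = xi[-1] = 0.0
        h = traj.h
        hess = np.array([float(harmonic_half_chain.potential_hess(
            traj.q[i], traj.t[i])[0, 0]) for i in range(traj.t.size)])
        stiff = np.sum(np.diff(xi) ** 2) / h
        pot = np.trapezoid(hess * xi ** 2, dx=h)
        direct = stiff - pot
        assert form.form_value(xi) == pytest.approx(direct, rel=1e-6)
        # and equals the matrix quadratic form on the interior values
        Q = form.matrix
        assert xi[1:-1] @ Q @ xi[1:-1] == pytest.approx(form.form_value(xi),
                                                        rel=1e-10)

    def test_non_stationary_trajectory_reports_residual(self, harmonic_half_chain):
        t = np.linspace(0, 2, 101)
        q = np.exp(t)[:, None]  # not a solution
        traj = Trajectory(t=t, q=q, v=q, chain=harmonic_half_chain)
        with pytest.raises(NonStationaryTrajectoryError) as exc:
            second_variation_form(harmonic_half_chain, traj)
        assert exc.value.residual > 1e-3

    def test_variation_function_endpoint_check(self):
        with pytest.raises(ValidationError, match="endpoint"):
            VariationFunction(t=np.linspace(0, 1, 5),
                              xi=np.array([0.0, 1.0, 2.0, 1.0, 0.5]))


class TestConjugatePoints:
    def test_harmonic_kinetic_focus_at_pi(self, harmonic_half_chain,
                                          harmonic_trajectory):
        pts = find_conjugate_points(harmonic_half_chain, harmonic_trajectory)
        assert len(pts) == 1
        assert pts[0].t_star == pytest.approx(np.pi, abs=2e-3)
        assert pts[0].multiplicity == 1

    def test_free_particle_none(self, free_chain):
        traj = integrate_trajectory(free_chain, 0.0, 0.5, 0.0, 10.0, 500)
        assert find_conjugate_points(free_chain, traj) == []
        assert jacobi_conjugate_points(free_chain, traj) == []

    def test_inverted_harmonic_none(self, inverted_chain):
        traj = integrate_trajectory(inverted_chain, 0.5, 0.25, 0.0, 3.0, 600)
        assert find_conjugate_points(inverted_chain, traj) == []
        assert jacobi_conjugate_points(inverted_chain, traj) == []

    def test_jacobi_harmonic_pi(self, harmonic_half_chain, harmonic_trajectory):
        pts = jacobi_conjugate_points(harmonic_half_chain, harmonic_trajectory)
        assert len(pts) == 1
        assert pts[0].t_star == pytest.approx(np.pi, abs=2e-3)

    def test_jacobi_omega_two_half_pi(self):
        chain = build_chain({"n_angles": 1, "inertias": 1.0,
                             "potential": {"kind": "harmonic_spring", "k": 4.0,
                                           "half_k": True}})
        traj = integrate_trajectory(chain, 1.0, 0.0, 0.0, 2.0, 800)
        pts = jacobi_conjugate_points(chain, traj)
        assert pts and pts[0].t_star == pytest.approx(np.pi / 2, abs=2e-3)

    def test_oracle_equivalence(self, harmonic_half_chain, free_chain,
                                inverted_chain):
        systems = [
            (harmonic_half_chain, (1.0, 0.0), 4.0),
            (free_chain, (0.0, 0.5), 4.0),
            (inverted_chain, (0.5, 0.25), 4.0),
        ]
        for chain, (q0, v0), t1 in systems:
            traj = integrate_trajectory(chain, q0, v0, 0.0, t1, 800)
            eig = find_conjugate_points(chain, traj)
            jac = jacobi_conjugate_points(chain, traj)
            assert len(eig) == len(jac)
            for a, b in zip(eig, jac):
                assert abs(a.t_star - b.t_star) < 10 * traj.h

    def test_multiplicity_two_isotropic_oscillator(self):
        chain = build_chain({"n_angles": 2, "inertias": 1.0,
                             "potential": {"kind": "harmonic_spring", "k": 1.0,
                                           "half_k": True}})
        traj = integrate_trajectory(chain, [1.0, 0.5], [0.0, 0.0], 0.0, 4.0, 400)
        pts = find_conjugate_points(chain, traj)
        assert len(pts) == 1
        assert pts[0].multiplicity == 2
        assert pts[0].t_star == pytest.approx(np.pi, abs=0.05)

    def test_morse_index_monotone_in_endpoint(self, harmonic_half_chain):
        traj = integrate_trajectory(harmonic_half_chain, 1.0, 0.0, 0.0, 7.0, 700)
        form = second_variation_form(harmonic_half_chain, traj)
        counts = form.negative_counts_by_endpoint(tol=form.zero_tolerance())
        assert np.all(np.diff(counts) >= 0)
        assert counts[-1] == 2  # conjugate points at pi and 2 pi on [0, 7]

    def test_minimality_before_first_conjugate_point(self, harmonic_half_chain):
        # random admissible perturbations never decrease the action before pi
        traj = integrate_trajectory(harmonic_half_chain, 1.0, 0.0, 0.0, 2.5, 500)
        S0 = action_integral(harmonic_half_chain, traj)
        rng = np.random.default_rng(13)
        for _ in range(10):
            xi = np.zeros(traj.t.size)
            # smooth random bump: a few Fourier modes
            for k in range(1, 6):
                xi += rng.standard_normal() * np.sin(
                    k * np.pi * traj.t / traj.t[-1])
            eps = 0.01
            q = traj.q[:, 0] + eps * xi
            v = traj.v[:, 0] + eps * np.gradient(xi, traj.t)
            pert = Trajectory(t=traj.t, q=q[:, None], v=v[:, None],
                              chain=harmonic_half_chain)
            assert action_integral(harmonic_half_chain, pert) >= S0 - 1e-12

    def test_conjugate_time_converges_second_order(self, harmonic_half_chain):
        errs = []
        for n in (100, 200, 400):
            traj = integrate_trajectory(harmonic_half_chain, 1.0, 0.0,
                                        0.0, 4.0, n)
            pts = find_conjugate_points(harmonic_half_chain, traj,
                                        refine_tol=1e-7)
            errs.append(abs(pts[0].t_star - np.pi))
        assert errs[2] < errs[0]
        order = np.log2(errs[0] / errs[2]) / 2.0
        assert 1.4 < order < 2.8
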