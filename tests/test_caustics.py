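import numpy as np
import pytest

from foldcaustic import (
    analytic_action_surface,
    build_chain,
    detect_caustic,
    envelope_points,
    family_action_surface,
    find_conjugate_points,
    hessian_determinant_scan,
    saddle_check_beyond,
    shoot_family,
)
from foldcaustic.dynamics import TrajectoryFamily
from foldcaustic.errors import ValidationError


@pytest.fixture(scope="module")
def harmonic_family():
    chain = build_chain({"n_angles": 1, "inertias": 1.0,
                         "potential": {"kind": "harmonic_spring", "k": 1.0,
                                       "half_k": True}})
    fam = shoot_family(chain, lambda u: (1.0, u), np.linspace(-2, 2, 21),
                       0.0, 4.0, 1600)
    return chain, fam


@pytest.fixture(scope="module")
def harmonic_surface(harmonic_family):
    chain, fam = harmonic_family
    return family_action_surface(fam, chain)


def cusp_surface(n_u=301, n_x1=21, n_x2=41):
    S = lambda u, x1, x2: 0.25 * u ** 4 + 0.5 * x1 * u ** 2 + x2 * u
    return analytic_action_surface(
        S, np.linspace(-1.5, 1.5, n_u),
        [np.linspace(-1.2, -0.2, n_x1), np.linspace(-0.8, 0.8, n_x2)],
        ["x1", "x2"])


class TestFamilyActionSurface:
    def test_free_particle_closed_form(self, free_chain):
        # members start at u and adjust velocity to reach x_target at t1:
        # S(u, x) = m (x - u)^2 / (2 (t1 - t0))
        x_target, t1 = 0.5, 2.0
        u_grid = np.linspace(-1, 1, 11)
        fam = shoot_family(free_chain,
                           lambda u: (u, (x_target - u) / t1),
                           u_grid, 0.0, t1, 200)
        surf = family_action_surface(fam, free_chain)
        expected = (x_target - u_grid) ** 2 / (2 * t1)
        np.testing.assert_allclose(surf.S[:, -1], expected, atol=1e-10)
        # all members indeed arrive at x_target
        np.testing.assert_allclose(surf.x[:, -1, 0], x_target, atol=1e-10)

    def test_harmonic_convex_in_u_early(self, harmonic_surface):
        # closed form S(u, t) gives d2S/du2 = sin(2t)/2: convex while t < pi/2
        surf = harmonic_surface
        j = int(np.argmin(np.abs(surf.t - 0.5)))
        suu = surf.d2S_du2[1:-1, j]
        assert np.all(suu > 0)
        np.testing.assert_allclose(suu, np.sin(2 * 0.5) / 2, rtol=1e-3)

    def test_constant_family_u_independent(self, free_chain):
        trajs = shoot_family(free_chain, lambda u: (0.2, 0.1),
                             np.linspace(0, 1, 7), 0.0, 1.0, 100)
        surf = family_action_surface(trajs, free_chain)
        assert np.all(np.abs(surf.dS_du[1:-1]) < 1e-14)

    def test_too_few_members_rejected(self, free_chain):
        fam = shoot_family(free_chain, lambda u: (u, 0.0),
                           np.linspace(0, 1, 4), 0.0, 1.0, 100)
        with pytest.raises(ValidationError, match="u-samples|members"):
            family_action_surface(fam, free_chain)


class TestDetectCaustic:
    def test_cusp_family_discriminant(self):
        surf = cusp_surface()
        dx2 = 1.6 / 40
        caustics = detect_caustic(surf, tol_first=dx2 / 2 * 1.01)
        assert len(caustics) > 10
        # every reported point lies on 4 x1^3 + 27 x2^2 = 0 within grid tolerance
        tol_disc = 27.0 * (dx2 / 2 * 1.01 + 5e-3) * 2.0
        for p in caustics:
            x1, x2 = p.x
            assert abs(4 * x1 ** 3 + 27 * x2 ** 2) < tol_disc

    def test_free_particle_family_empty(self, free_chain):
        # S convex in u everywhere -> no caustic
        fam = shoot_family(free_chain, lambda u: (u, (0.5 - u) / 2.0),
                           np.linspace(-1, 1, 11), 0.0, 2.0, 200)
        surf = family_action_surface(fam, free_chain)
        assert len(detect_caustic(surf)) == 0

    def test_harmonic_focus_point(self, harmonic_surface):
        caustics = detect_caustic(harmonic_surface)
        assert len(caustics) == 1
        p = caustics.points[0]
        assert p.kind == "focus"
        assert p.t == pytest.approx(np.pi, abs=5e-3)
        assert p.x[0] == pytest.approx(-1.0, abs=5e-3)

    def test_detection_stable_under_grid_refinement(self):
        coarse = cusp_surface(n_u=151, n_x1=11, n_x2=21)
        fine = cusp_surface(n_u=301, n_x1=21, n_x2=41)
        c_pts = detect_caustic(coarse, tol_first=(1.6 / 20) / 2 * 1.01)
        f_pts = detect_caustic(fine, tol_first=(1.6 / 40) / 2 * 1.01)
        assert len(c_pts) and len(f_pts)
        cell = np.array([1.0 / 10, 1.6 / 20])  # coarse cell sizes
        f_arr = np.array([p.x for p in f_pts])
        for p in c_pts:
            d = np.abs(f_arr - np.array(p.x)) / cell
            assert np.min(np.max(d, axis=1)) <= 1.0


class TestEnvelope:
    def test_harmonic_envelope_collapses_to_focus(self, harmonic_family):
        _, fam = harmonic_family
        pts = envelope_points(fam)
        assert len(pts) >= 5
        for p in pts:
            assert p.t == pytest.approx(np.pi, abs=1e-2)
            assert p.x[0] == pytest.approx(-1.0, abs=1e-2)

    def test_parallel_free_family_no_envelope(self, free_chain):
        fam = shoot_family(free_chain, lambda u: (u, 0.3),
                           np.linspace(-1, 1, 9), 0.0, 2.0, 100)
        assert envelope_points(fam) == []

    def test_projectile_safety_parabola(self):
        # 2-angle analogue: free horizontal coordinate, uniform force on the
        # second; launch speed 1 at angle u -> envelope y = 1/2 - x^2/2
        chain = build_chain({
            "n_angles": 2, "inertias": 1.0,
            "potential": [{"kind": "free"},
                          {"kind": "custom", "expression": "theta"}]})
        fam = shoot_family(chain, lambda u: ((0.0, 0.0), (np.cos(u), np.sin(u))),
                           np.linspace(0.35, 1.25, 19), 0.0, 2.2, 400)
        pts = envelope_points(fam)
        assert len(pts) >= 10
        for p in pts:
            x, y = p.x
            assert y == pytest.approx(0.5 - 0.5 * x ** 2, abs=2e-2)

    def test_envelope_agrees_with_caustic(self, harmonic_family,
                                          harmonic_surface):
        _, fam = harmonic_family
        caustics = detect_caustic(harmonic_surface)
        env = envelope_points(fam)
        p = caustics.points[0]
        dt = float(fam.t[1] - fam.t[0])
        x_cell = float(np.ptp(harmonic_surface.x)) / fam.u.size
        best = min(env, key=lambda e: abs(e.t - p.t))
        assert abs(best.t - p.t) <= 5 * max(dt, 1e-6) + 5e-3
        assert abs(best.x[0] - p.x[0]) <= 5 * x_cell

    def test_caustic_time_equals_conjugate_point(self, harmonic_family,
                                                 harmonic_surface):
        chain, fam = harmonic_family
        p = detect_caustic(harmonic_surface).points[0]
        member = fam.member_nearest(p.u)
        cps = find_conjugate_points(chain, member)
        assert len(cps) == 1
        assert abs(cps[0].t_star - p.t) < 10 * member.h


class TestHessianScan:
    def test_one_dimensional_reduces_to_second_derivative(self):
        # S(u) = u^4/4 + x1 u^2/2 at x1 = -0.3: det H = 3u^2 + x1
        x1 = -0.3
        hits = hessian_determinant_scan(
            lambda u: 0.25 * u ** 4 + 0.5 * x1 * u ** 2,
            [np.linspace(-1, 1, 401)], tol=0.02)
        assert hits
        roots = np.sqrt(-x1 / 3.0)
        for hit in hits:
            assert min(abs(hit["point"][0] - roots),
                       abs(hit["point"][0] + roots)) < 0.02

    def test_quadratic_field_no_zeros(self):
        hits = hessian_determinant_scan(
            lambda x, y: 0.5 * (x ** 2 + y ** 2),
            [np.linspace(-1, 1, 21), np.linspace(-1, 1, 21)], tol=1e-3)
        assert hits == []

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValidationError, match="coarse"):
            hessian_determinant_scan(lambda u: u ** 2, [np.linspace(0, 1, 4)])


class TestSaddleCheckBeyond:
    def test_harmonic_signature_flips_at_focus(self, harmonic_surface):
        caustics = detect_caustic(harmonic_surface)
        reports = saddle_check_beyond(harmonic_surface, caustics)
        assert len(reports) == 1
        rep = reports[0]
        assert rep["status"] == "confirmed"
        assert rep["before"]["n_neg"] == 0
        assert rep["after"]["n_neg"] == 1

    def test_free_family_empty_report(self, free_chain):
        fam = shoot_family(free_chain, lambda u: (u, 0.1),
                           np.linspace(-1, 1, 9), 0.0, 2.0, 100)
        surf = family_action_surface(fam, free_chain)
        caustics = detect_caustic(surf)
        assert saddle_check_beyond(surf, caustics) == []

    def test_cusp_fold_crossing_loses_one_direction(self):
        surf = cusp_surface()
        caustics = detect_caustic(surf, tol_first=(1.6 / 40) / 2 * 1.01)
        reports = saddle_check_beyond(surf, caustics)
        confirmed = [r for r in reports if r["status"] == "confirmed"]
        assert len(confirmed) >= len(reports) // 2
        for rep in confirmed:
            # crossing the fold line a max/min pair is created or destroyed
            d_neg = abs(rep["after"]["n_neg"] - rep["before"]["n_neg"])
            assert d_neg == 1

    def test_caustic_at_boundary_unconfirmable(self, harmonic_family):
        chain, _ = harmonic_family
        # family truncated just past the focus: no room beyond
        fam = shoot_family(chain, lambda u: (1.0, u), np.linspace(-2, 2, 21),
                           0.0, np.pi + 0.01, 800)
        surf = family_action_surface(fam, chain)
        caustics = detect_caustic(surf)
        if len(caustics):
            reports = saddle_check_beyond(surf, caustics)
            assert all(r["status"] == "unconfirmable" for r in reports)
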