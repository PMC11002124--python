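"""VPP placement, pivot vectors, least-squares split and dispatch."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vppgrf as v
from vppgrf.errors import IllConditionedError, ValidationError
from vppgrf.solver import FLAG_CLAMPED, _solve_pairs


SUB18 = v.SubjectParams(M=800.0 / 9.81, BH=1.80)
P09 = v.VppParams(vppscale=0.9)


class TestVppPlacement:
    def test_vertical_force_gives_planar_com(self):
        vpp, degen = v.compute_vpp([0, 0, 1.0], [0, 0, 800.0], P09, SUB18)
        np.testing.assert_allclose(vpp[0], [0.0, 0.0, 1.62], atol=1e-12)
        assert not degen[0]

    def test_tilted_force_offsets_planar_position(self):
        # offset = (COM_z / F_z) * F_xy = (1.0/800)*80 = 0.1
        vpp, _ = v.compute_vpp([0, 0, 1.0], [80.0, 0, 800.0], P09, SUB18)
        np.testing.assert_allclose(vpp[0], [0.1, 0.0, 1.62], atol=1e-12)

    def test_zero_vertical_force_falls_back_to_com(self):
        vpp, degen = v.compute_vpp([0.3, -0.1, 1.0], [50.0, 0.0, 0.0], P09, SUB18)
        assert degen[0]
        np.testing.assert_allclose(vpp[0, :2], [0.3, -0.1], atol=1e-15)
        assert vpp[0, 2] == pytest.approx(1.62)

    def test_time_varying_scale_hook(self):
        com = np.tile([0.0, 0.0, 1.0], (3, 1))
        f = np.tile([0.0, 0.0, 800.0], (3, 1))
        vpp, _ = v.compute_vpp(com, f, P09, SUB18, vppscale=np.array([0.5, 0.9, 1.4]))
        np.testing.assert_allclose(vpp[:, 2], np.array([0.5, 0.9, 1.4]) * 1.80, atol=1e-12)


class TestVpv:
    def test_vertical_line(self):
        np.testing.assert_allclose(
            v.compute_vpv([0, 0, 1.62], [0, 0, 0]), [0, 0, 1], atol=1e-15
        )

    def test_oblique_example(self):
        u = v.compute_vpv(np.array([0, 0, 1.62]), np.array([0, 0.2, 0.0]))
        np.testing.assert_allclose(u, [0.0, -0.12253, 0.99246], atol=1e-5)
        assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValidationError):
            v.compute_vpv([0.1, 0.2, 0.0], [0.1, 0.2, 0.0])


class TestDoubleSupportSolve:
    def test_symmetric_squat_analytic(self):
        """Equal-opposite lateral forces from a purely vertical resultant."""
        vpp, _ = v.compute_vpp([0, 0, 1.0], [0, 0, 800.0], P09, SUB18)
        ul = v.compute_vpv(vpp[0], np.array([0.0, 0.2, 0.0]))
        ur = v.compute_vpv(vpp[0], np.array([0.0, -0.2, 0.0]))
        a, b, res = v.solve_double_support(np.array([0, 0, 800.0]), ul, ur)
        assert a == pytest.approx(403.04, abs=0.01)
        assert b == pytest.approx(403.04, abs=0.01)
        grf_l, grf_r = a * ul, b * ur
        assert grf_l[1] == pytest.approx(-49.39, abs=0.01)
        assert grf_r[1] == pytest.approx(+49.39, abs=0.01)
        assert grf_l[2] == pytest.approx(400.0, abs=0.01)
        assert res == pytest.approx(0.0, abs=1e-9)

    def test_exact_representation_along_one_direction(self):
        ul = np.array([0.0, -0.12, 0.99277389])
        ul /= np.linalg.norm(ul)
        ur = np.array([0.3, 0.1, 0.9])
        ur /= np.linalg.norm(ur)
        f = 500.0 * ul
        a, b, res = v.solve_double_support(f, ul, ur)
        assert a == pytest.approx(500.0, rel=1e-12)
        assert b == pytest.approx(0.0, abs=1e-9)
        assert res <= 1e-9 * 500.0

    @given(st.integers(min_value=0, max_value=10_000))
    def test_consistent_instance_recovery(self, seed):
        """F built as a·ul + b·ur is decomposed back into exactly (a, b)."""
        rng = np.random.default_rng(seed)
        ul = rng.normal(size=3)
        ur = rng.normal(size=3)
        ul /= np.linalg.norm(ul)
        ur /= np.linalg.norm(ur)
        if abs(ul @ ur) > 0.99:
            return
        a_true, b_true = rng.uniform(10.0, 900.0, size=2)
        f = a_true * ul + b_true * ur
        a, b, res = v.solve_double_support(f, ul, ur)
        assert a == pytest.approx(a_true, rel=1e-9)
        assert b == pytest.approx(b_true, rel=1e-9)
        assert res <= 1e-9 * np.linalg.norm(f)

    def test_matches_numpy_lstsq_with_out_of_plane_residual(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            ul, ur = rng.normal(size=(2, 3))
            ul /= np.linalg.norm(ul)
            ur /= np.linalg.norm(ur)
            if abs(ul @ ur) > 0.99:
                continue
            f = rng.normal(scale=400.0, size=3)
            A = np.c_[ul, ur]
            x, *_ = np.linalg.lstsq(A, f, rcond=None)
            res_np = np.linalg.norm(A @ x - f)
            params = v.VppParams(nonneg_policy="allow_negative")
            a, b, res = v.solve_double_support(f, ul, ur, params)
            np.testing.assert_allclose([a, b], x, rtol=1e-9, atol=1e-9)
            assert res == pytest.approx(res_np, rel=1e-9, abs=1e-9)

    def test_residual_matches_projection_oracle(self):
        """Reported residual equals |F·n| for n the unit normal of span{ul, ur}."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            ul, ur = rng.normal(size=(2, 3))
            ul /= np.linalg.norm(ul)
            ur /= np.linalg.norm(ur)
            if abs(ul @ ur) > 0.95:
                continue
            n = np.cross(ul, ur)
            n /= np.linalg.norm(n)
            a_t, b_t = rng.uniform(50.0, 600.0, size=2)
            c = rng.normal(scale=30.0)
            f = a_t * ul + b_t * ur + c * n
            a, b, res = v.solve_double_support(f, ul, ur)
            assert res == pytest.approx(abs(c), rel=1e-9, abs=1e-9)
            # in-plane part reproduced despite the out-of-plane component
            assert a == pytest.approx(a_t, rel=1e-9)
            assert b == pytest.approx(b_t, rel=1e-9)

    def test_clamp_reassign_zeroes_negative_foot(self):
        ul = np.array([0.3, 0.0, 0.95393920141695])
        ul /= np.linalg.norm(ul)
        ur = np.array([-0.3, 0.0, 0.95393920141695])
        ur /= np.linalg.norm(ur)
        # force tilted beyond the cone: raw LS would need b < 0
        f = 700.0 * ul - 50.0 * ur
        a, b, res, flags = _solve_pairs(f, ul, ur, v.VppParams())
        assert flags[0] & FLAG_CLAMPED
        assert b[0] == 0.0
        assert a[0] == pytest.approx(float(ul @ f), rel=1e-12)  # 1-D projection
        raw_a, raw_b, _, _ = _solve_pairs(f, ul, ur, v.VppParams(nonneg_policy="allow_negative"))
        assert raw_b[0] < 0.0

    def test_parallel_directions_raise(self):
        u = np.array([0.0, 0.0, 1.0])
        with pytest.raises(IllConditionedError):
            v.solve_double_support(np.array([0, 0, 800.0]), u, u)


class TestPredictDispatch:
    def test_single_support_and_flight(self, subject):
        n = 9
        t = np.arange(n) / 100.0
        com = v.Trajectory(t, np.tile([0, 0, 0.9], (n, 1)))
        f = v.compute_com_force(com, subject)
        cop = np.tile([0.05, 0.0, 0.0], (n, 1))
        fc = v.FootContact(np.ones((n, 1)), np.ones(n), cop.copy(), np.ones(n, bool))
        labels = np.array(["single_L"] * 3 + ["flight"] * 3 + ["single_R"] * 3)
        sol = v.predict_grf(f, com, fc, fc, labels, v.VppParams(), subject)
        np.testing.assert_array_equal(sol.grf_l[:3], f.v[:3])
        np.testing.assert_array_equal(sol.grf_r[:3], 0.0)
        np.testing.assert_array_equal(sol.grf_l[3:6], 0.0)
        np.testing.assert_array_equal(sol.grf_r[3:6], 0.0)
        np.testing.assert_array_equal(sol.grf_r[6:], f.v[6:])
        assert not sol.flags.any()

    def test_grf_lines_pass_through_vpp(self, lunge_trial):
        sol = v.predict_for_trial(
            lunge_trial, v.VppParams(vppscale=lunge_trial.true_vppscale)
        )
        d = sol.labels == "double"
        for grf, cop in ((sol.grf_l, sol.cop_l), (sol.grf_r, sol.cop_r)):
            u = grf[d] / np.linalg.norm(grf[d], axis=1, keepdims=True)
            # distance from the VPP to the line through the COP along the GRF
            w = sol.vpp[d] - cop[d]
            dist = np.linalg.norm(np.cross(u, w), axis=1)
            assert dist.max() <= 1e-9

    def test_mirror_symmetry_swaps_feet_exactly(self, lunge_trial):
        tr = lunge_trial
        params = v.VppParams(vppscale=0.8)
        com, f, fc_l, fc_r, labels = v.prepare_trial(tr)
        sol = v.predict_grf(f, com, fc_l, fc_r, labels, params, tr.subject)

        def mirror_traj(traj):
            w = traj.v.copy()
            w[:, 1] *= -1.0
            return traj.with_values(w)

        def mirror_contact(fc):
            cop = fc.cop.copy()
            cop[:, 1] *= -1.0
            return v.FootContact(fc.weights.copy(), fc.w_total.copy(), cop, fc.defined.copy())

        swap = {"single_L": "single_R", "single_R": "single_L"}
        labels_m = np.array([swap.get(l, l) for l in labels])
        sol_m = v.predict_grf(
            mirror_traj(f), mirror_traj(com), mirror_contact(fc_r),
            mirror_contact(fc_l), labels_m, params, tr.subject,
        )
        flip = np.array([1.0, -1.0, 1.0])
        np.testing.assert_array_equal(sol_m.grf_l, sol.grf_r * flip)
        np.testing.assert_array_equal(sol_m.grf_r, sol.grf_l * flip)

    def test_vppscale_plateau_above_optimum(self, squat_trial):
        """RMSE varies much less per grid step above ~0.9 than below 0.8."""
        sw = v.sweep_vppscale(squat_trial)
        s, total = sw.scales, sw.total
        below = np.abs(np.diff(total[s <= 0.8])).mean()
        above = np.abs(np.diff(total[s >= 0.9])).mean()
        assert above < below
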