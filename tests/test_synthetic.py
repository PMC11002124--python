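"""Generator invariants: closure, round trips, determinism, phase structure."""

import collections

import numpy as np
import pytest

import vppgrf as v
from conftest import max_rel_grf_error


class TestRoundTrip:
    @pytest.mark.parametrize("kind", ["squat", "lunge", "walk"])
    @pytest.mark.parametrize("scale", [0.5, 0.9, 1.4])
    def test_prediction_reproduces_truth(self, kind, scale):
        trial = v.simulate(kind, true_vppscale=scale)
        sol = v.predict_for_trial(trial, v.VppParams(vppscale=scale))
        assert max_rel_grf_error(sol, trial) <= 1e-9
        assert not sol.flags.any()

    def test_truth_satisfies_closure(self, walk_trial, squat_trial, lunge_trial):
        for trial in (walk_trial, squat_trial, lunge_trial):
            v.validate_trial(trial)  # raises on violation

    def test_truth_lines_pass_through_true_vpp(self, lunge_trial):
        tr = lunge_trial
        f = v.compute_com_force(tr.com_clean, tr.subject)
        d = tr.labels == "double"
        vpp, _ = v.compute_vpp(
            tr.com_clean.v[d], f.v[d], v.VppParams(vppscale=tr.true_vppscale), tr.subject
        )
        for grf, cop in ((tr.truth_grf_l[d], tr.truth_cop_l[d]),
                         (tr.truth_grf_r[d], tr.truth_cop_r[d])):
            u = grf / np.linalg.norm(grf, axis=1, keepdims=True)
            dist = np.linalg.norm(np.cross(u, vpp - cop), axis=1)
            assert dist.max() <= 1e-9


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = v.simulate_squat(noise_sigma=0.002, seed=123)
        b = v.simulate_squat(noise_sigma=0.002, seed=123)
        np.testing.assert_array_equal(a.com.v, b.com.v)
        np.testing.assert_array_equal(a.contacts_l.p, b.contacts_l.p)
        np.testing.assert_array_equal(a.truth_grf_l, b.truth_grf_l)

    def test_different_seed_differs_with_noise(self):
        a = v.simulate_squat(noise_sigma=0.002, seed=1)
        b = v.simulate_squat(noise_sigma=0.002, seed=2)
        assert not np.array_equal(a.com.v, b.com.v)
        np.testing.assert_array_equal(a.com_clean.v, b.com_clean.v)


class TestSquat:
    def test_zero_depth_is_static_standing(self, subject):
        trial = v.simulate_squat(subject=subject, depth=0.0)
        bw = subject.BW
        # vertical halves summing to BW, laterals equal and opposite
        np.testing.assert_allclose(trial.truth_grf_l[:, 2], bw / 2, atol=1e-9)
        np.testing.assert_allclose(trial.truth_grf_r[:, 2], bw / 2, atol=1e-9)
        np.testing.assert_allclose(
            trial.truth_grf_l[:, 1], -trial.truth_grf_r[:, 1], atol=1e-9
        )
        assert np.all(np.abs(trial.truth_grf_l[:, 1]) > 1.0)  # genuinely non-zero
        np.testing.assert_allclose(trial.truth_grf_l[:, 0], 0.0, atol=1e-9)

    def test_noise_applied_to_export_only(self):
        trial = v.simulate_squat(noise_sigma=0.005, seed=4)
        dev = np.abs(trial.com.v - trial.com_clean.v)
        assert dev.max() > 1e-4
        # truth rebuilt from the clean COM still closes
        v.validate_trial(trial)

    def test_excessive_depth_rejected(self, subject):
        with pytest.raises(v.ValidationError):
            v.simulate_squat(subject=subject, depth=2.0)


class TestLunge:
    def test_anterior_components_opposite_signs(self, lunge_trial):
        tr = lunge_trial
        mid = tr.n // 2
        ax_l = tr.truth_grf_l[mid, 0]
        ax_r = tr.truth_grf_r[mid, 0]
        assert ax_l * ax_r < 0.0
        # left foot is anterior: its GRF tilts backwards toward the pivot
        assert ax_l < 0.0 < ax_r

    def test_vertical_components_sum_to_resultant(self, lunge_trial):
        f = v.compute_com_force(lunge_trial.com_clean, lunge_trial.subject)
        np.testing.assert_allclose(
            lunge_trial.truth_grf_l[:, 2] + lunge_trial.truth_grf_r[:, 2],
            f.v[:, 2],
            atol=1e-9 * lunge_trial.subject.BW,
        )

    def test_zero_stride_recovers_squat(self):
        lunge = v.simulate_lunge(stride=0.0, depth=0.4, stance_width=0.4)
        squat = v.simulate_squat(depth=0.4, stance_width=0.4)
        np.testing.assert_allclose(lunge.truth_grf_l, squat.truth_grf_l, atol=1e-9)
        np.testing.assert_allclose(lunge.truth_grf_r, squat.truth_grf_r, atol=1e-9)


class TestWalk:
    def test_phase_structure(self, walk_trial):
        counts = collections.Counter(walk_trial.labels)
        assert set(counts) == {"double", "single_L", "single_R"}

    def test_double_support_durations(self, walk_trial):
        labels = walk_trial.labels
        fs = walk_trial.sample_rate
        designed = walk_trial.meta["ds_fraction"] * walk_trial.meta["step_period"] * fs
        runs = []
        run = 0
        for lab in labels:
            if lab == "double":
                run += 1
            elif run:
                runs.append(run)
                run = 0
        if run:
            runs.append(run)
        assert len(runs) == 5  # one per touchdown
        for r in runs:
            # smooth load/unload ramps extend contact a few frames each side
            assert designed - 1 <= r <= designed + 9

    def test_single_support_unloads_swing_foot(self, walk_trial):
        sl = walk_trial.labels == "single_L"
        sr = walk_trial.labels == "single_R"
        np.testing.assert_array_equal(walk_trial.truth_grf_r[sl], 0.0)
        np.testing.assert_array_equal(walk_trial.truth_grf_l[sr], 0.0)

    def test_mean_vertical_force_over_stride_is_body_weight(self, walk_trial):
        """Impulse balance: over a full periodic stride the mean vertical GRF
        must carry body weight (within 2%)."""
        fs = walk_trial.sample_rate
        t0 = walk_trial.meta["first_touchdown_time"]
        T = walk_trial.meta["step_period"]
        i0 = int(round((t0 + T) * fs))
        i1 = int(round((t0 + 3 * T) * fs))  # one stride = two steps
        fz = walk_trial.truth_grf_l[i0:i1, 2] + walk_trial.truth_grf_r[i0:i1, 2]
        assert fz.mean() == pytest.approx(walk_trial.subject.BW, rel=0.02)

    def test_cop_travels_forward_during_stance(self, walk_trial):
        cop_x = walk_trial.truth_cop_l[:, 0]
        ok = ~np.isnan(cop_x)
        # within the first left stance the COP progresses heel to toe
        idx = np.flatnonzero(ok)
        first_stance = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)[0]
        travel = cop_x[first_stance[-1]] - cop_x[first_stance[0]]
        assert travel > 0.1

    def test_invalid_ds_fraction_rejected(self):
        with pytest.raises(v.ValidationError):
            v.simulate_walk(ds_fraction=0.6)


class TestNoiseScaling:
    def test_rmse_at_true_scale_monotone_in_noise(self):
        """Doubling COM noise does not decrease sweep RMSE at the true scale
        (averaged over 10 seeds)."""
        grid = np.array([0.9])
        means = []
        for sigma in (0.002, 0.004):
            vals = []
            for seed in range(10):
                trial = v.simulate_squat(noise_sigma=sigma, seed=seed)
                sw = v.sweep_vppscale(trial, grid=grid, com_cutoff_hz=3.0)
                vals.append(sw.total[0])
            means.append(np.mean(vals))
        assert means[1] >= means[0]
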