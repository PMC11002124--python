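"""Why a pivot: lateral foot forces invisible to COM-only inverse dynamics.

During a squat the COM barely accelerates sideways, so the resultant COM
force has (near) zero lateral component — yet force plates show clearly
non-zero, equal-and-opposite lateral forces under the two feet.  Splitting
the resultant 50/50 between the feet therefore predicts zero lateral force;
routing each foot's force through the virtual pivot point reproduces the
lateral components exactly.
"""

import vppgrf as v

trial = v.simulate_squat(true_vppscale=0.9, seed=0)
com, f_com, fc_l, fc_r, labels = v.prepare_trial(trial)

base_l, base_r = v.baseline_even_split(f_com, labels)
sol = v.predict_grf(f_com, com, fc_l, fc_r, labels,
                    v.VppParams(vppscale=0.9), trial.subject)

rmse_base = v.rmse_by_direction(base_l, base_r,
                                trial.truth_grf_l, trial.truth_grf_r, trial.subject)
rmse_vpp = v.rmse_by_direction(sol.grf_l, sol.grf_r,
                               trial.truth_grf_l, trial.truth_grf_r, trial.subject)

i = trial.n // 2
print(f"mid-trial truth lateral forces:  left {trial.truth_grf_l[i, 1]:+.1f} N, "
      f"right {trial.truth_grf_r[i, 1]:+.1f} N")
print(f"COM-only even split predicts:    left {base_l[i, 1]:+.1f} N, "
      f"right {base_r[i, 1]:+.1f} N")
print(f"pivot-point method predicts:     left {sol.grf_l[i, 1]:+.1f} N, "
      f"right {sol.grf_r[i, 1]:+.1f} N")
print(f"\nlateral RMSE (BW):  even split {rmse_base[1]:.4f},  "
      f"pivot method {rmse_vpp[1]:.2e}")
print("The even split misses ~0.06 BW of lateral force entirely; the pivot")
print("decomposition recovers it to numerical precision.")
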