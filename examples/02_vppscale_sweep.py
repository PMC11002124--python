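"""Sweep the pivot height scale and recover the value used to build a trial.

The VPPscale (pivot height / body height) is varied over 0.2..2.0 in steps
of 0.1; at each value the GRF prediction is rerun and scored against the
reference forces as a per-direction RMSE in body-weight (BW) units.  On a
noiseless trial the summed RMSE has its minimum exactly at the true scale;
with 2 mm COM position noise the COM is low-pass filtered at 3 Hz (about six
times the movement fundamental) before differentiation and the optimum still
lands on or next to the truth.
"""

import vppgrf as v

clean = v.simulate_squat(true_vppscale=0.9, seed=0)
sw = v.sweep_vppscale(clean)
print("scale   RMSE_ant  RMSE_lat  RMSE_vert  (BW)")
for s, row in zip(sw.scales, sw.rmse):
    marker = "  <- optimum" if s == sw.optimum else ""
    print(f"{s:4.1f}   {row[0]:8.4f}  {row[1]:8.4f}  {row[2]:9.4f}{marker}")
print(f"\nnoiseless optimum: {sw.optimum:.1f} (true scale 0.9)")

optima = []
for seed in range(5):
    noisy = v.simulate_squat(true_vppscale=0.9, noise_sigma=0.002, seed=seed)
    optima.append(v.sweep_vppscale(noisy, com_cutoff_hz=3.0).optimum)
print(f"optima under 2 mm COM noise (5 seeds): {optima}")
print("Each optimum is the grid argmin of the summed directional RMSE; the")
print("lateral column is what actually discriminates the pivot height.")
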