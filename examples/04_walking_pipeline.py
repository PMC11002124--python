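"""Walking: support phases, file round trip and double-step segmentation.

A walking trial alternates single and double support; the contact model
labels each frame from the 18 contact points per foot, the solver dispatches
accordingly (single support: whole resultant at the stance foot; double
support: pivot decomposition), and the analysis window is one double step
between successive left-foot touchdowns.  The trial is also written to CSV
and read back to show the file interface.
"""

import collections
import tempfile
from pathlib import Path

import vppgrf as v

trial = v.simulate_walk(speed=1.2, step_length=0.65, seed=0)
counts = collections.Counter(trial.labels)
print(f"{trial.n} frames: " + ", ".join(f"{k} {n}" for k, n in sorted(counts.items())))

seg = v.segment_trial("walking", trial.com, trial.labels)
print(f"double-step segment: frames [{seg.start}, {seg.end}] "
      f"({(seg.end - seg.start + 1) / trial.sample_rate:.2f} s, rule: {seg.rule})")

sol = v.predict_for_trial(trial, v.VppParams(vppscale=trial.true_vppscale))
rmse = v.rmse_by_direction(sol.grf_l[seg.start:seg.end + 1],
                           sol.grf_r[seg.start:seg.end + 1],
                           trial.truth_grf_l[seg.start:seg.end + 1],
                           trial.truth_grf_r[seg.start:seg.end + 1],
                           trial.subject)
print(f"RMSE over the segment at the true scale (BW): "
      f"anterior {rmse[0]:.2e}, lateral {rmse[1]:.2e}, vertical {rmse[2]:.2e}")

with tempfile.TemporaryDirectory() as tmp:
    prefix = Path(tmp) / "walk"
    v.save_trial(trial, prefix)
    files = sorted(p.name for p in Path(tmp).iterdir())
    loaded = v.load_trial(prefix)
    print(f"\nwrote {files}; reloaded {loaded.n} frames losslessly "
          f"({'identical' if (loaded.com.v == trial.com.v).all() else 'DIFFERENT'})")
print("Near-zero RMSE at the true scale shows the decomposition is exact on")
print("clean kinematics; measured data adds noise and model error on top.")
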