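# Methods

## Model overview

The package predicts per-foot three-dimensional ground reaction forces
(GRFs) from whole-body kinematics under three assumptions:

1. **Newton's law for the whole body.** With ground contact as the only
   external contact force, the resultant acting at the centre of mass is
   `F_COM(t) = M·a_COM(t) + M·g·ẑ`, and it equals the total GRF. The static
   weight term is written out explicitly so that quiet standing yields
   `F_COM = (0, 0, BW)` rather than zero.
2. **Support-phase dispatch.** During single support the whole resultant
   acts at the stance foot's centre of pressure (COP); during flight both
   GRFs vanish; during double support the split is indeterminate and the
   virtual pivot point closes the system.
3. **Virtual pivot point (VPP).** The per-foot force directions point from
   each COP to a common pivot whose horizontal position is
   `VPP(x,y) = COM(x,y) + COM(z)/F_COM(z)·F_COM(x,y)` and whose height is
   `VPP(z) = VPPscale·BH`. We implement the horizontal placement exactly as
   written, with the height override independent of it, and do not
   reinterpret it geometrically (e.g. as a ground intersection).

Coordinates are a right-handed lab frame: x anterior, y left-lateral,
z vertical up, ground plane z = 0. All file units are SI (s, m, N);
body-weight (BW = M·g) normalisation appears only in evaluation outputs.

## Contact model

Each foot carries `n_cp = 18` contact points (a deterministic 2/4/8/4
heel–midfoot–forefoot–toe grid over the sole rectangle, "layout v1";
results should cite the layout version since the exact placement is a
modelling choice). Point `i` contributes weight
`W_i = WP(z_i)·WV(‖v_i(x,y)‖)` with raised-cosine ramps

    WP(z) = 1 for z ≤ 0.8·z_lim, 0 for z ≥ z_lim, cosine blend between,
    WV(v) = 1 for v ≤ 0.15·v_lim, 0 for v ≥ v_lim, cosine blend between,

`z_lim = 0.04 m`, `v_lim = 1.3 m/s`. Taken literally the cosine expressions
oscillate outside the transition band; since they are meant to be a smooth
transition between no contact and full contact, we clamp to the plateau
values outside the band — the only monotone reading.

The COP is the weight-weighted mean of contact-point positions, projected
onto the ground plane (a centre of pressure lives on the contact surface;
the projection is configurable off). Frames whose total weight falls below
`w_support_threshold = 0.05` get an *undefined* COP (NaN, flagged) instead
of a 0/0 error, and that foot counts as airborne for phase classification:
double / single_L / single_R / flight from the two feet's defined flags.
Contact-point velocities come from the same finite-difference stencils as
the COM acceleration (below).

## Solver

With unit pivot vectors `u_L, u_R`, force closure
`F = a·u_L + b·u_R` is solved via the closed-form normal equations
`[[1, c], [c, 1]]·(a,b)ᵀ = (u_L·F, u_R·F)`, `c = u_L·u_R` — the unique
minimum-residual least-squares solution for independent directions (the
standard semantics of the matrix left-division operator on a 3×2 system;
cross-checked against `numpy.linalg.lstsq` in the tests). The reported
residual is the out-of-plane component `‖a·u_L + b·u_R − F‖`.

Guards, each flagged per frame rather than fatal:

- **Degenerate vertical force** (`|F_COM(z)| < eps_fz`, default 1e-6·BW):
  the planar pivot placement divides by `F_COM(z)`; such frames fall back
  to `VPP(x,y) = COM(x,y)`.
- **Ill-conditioning** (condition number `sqrt((1+|c|)/(1−|c|))` above
  `cond_limit = 1e8`, i.e. near-parallel pivot vectors from nearly
  coincident COPs): the resultant is split 50/50 along the mean direction.
- **Negative magnitudes**: unilateral contact cannot pull a foot down, so
  under the default `clamp_reassign` policy a negative magnitude is set to
  zero and the other foot refit as the 1-D projection of `F` onto its
  direction (one step of an active-set non-negative solve);
  `allow_negative` retains the raw algebraic solution for comparisons.

A per-frame `VPPscale` series can be supplied (the pivot plausibly differs
between support phases), but the default is a single constant for the whole
trial, including single support, where the pivot is bypassed entirely.

## Evaluation

RMSE against reference forces is computed per direction (anterior, lateral,
vertical), pooling both feet — `sqrt(mean over frames and feet of
(pred−ref)²)/BW` — matching per-direction reporting granularity. The scale
sweep reruns the prediction over the grid 0.2:0.1:2.0 (19 values; the
contact model and `F_COM` are scale-independent and computed once). Across
trials the optimum is a fixed, reproducible rule replacing by-eye selection:
the grid argmin of the median (across trials) of the summed directional
RMSE, exact ties broken toward the smaller scale. Sweep curves remain
available for visual inspection (`evaluation.plot_sweep`).

Segmentation: squats and lunges run from the first frame where the smoothed
COM vertical velocity drops below −0.02 m/s to the last frame where it
exceeds +0.02 m/s (the threshold is our choice; the velocity is low-passed
at 6 Hz by default before thresholding). Walking runs from one left-foot
touchdown (rising edge of left contact) to the frame before the next —
one double step.

### Smoothing noisy kinematics

Differentiating measured positions twice amplifies noise by ω²; the
pipeline therefore optionally zero-phase low-pass filters the COM before
differentiation (`com_cutoff_hz`). The cutoff should track the movement
bandwidth: about **six times the movement's fundamental frequency** — 6 Hz
for ~1 Hz gait (the classic kinematics recommendation), 3 Hz for a squat
with a 2 s cycle. This matters for pivot-height identification
specifically: with white position noise σ = 2 mm at 120 Hz, a 6 Hz cutoff
leaves ≈0.05 BW of horizontal force noise, and absorbing a lateral noise
force from a tall pivot requires a large left/right magnitude imbalance
(the lateral components of the pivot directions shrink as 1/scale), which
inflates vertical RMSE with scale and biases the sweep argmin low. At the
bandwidth-matched 3 Hz the true scale 0.9 is recovered exactly in ≥18 of 20
seeded squat trials and always within one grid step.

Measured force/COP signals use zero-phase Butterworth cutoffs of 20 Hz and
40 Hz respectively (order 2 per pass, a configuration choice since the
original order is unstated). The forward-backward pass uses Gustafsson
initial conditions, which preserve DC exactly and make the filter exactly
time-reversal symmetric. A plain odd-window running-median utility is
provided for impulsive noise but is not part of the reference pipeline.

## Numerical differentiation

Second-order central differences at interior samples; second-order
one-sided stencils at the endpoints (four-point for the second derivative,
falling back to the adjacent interior value when only three samples exist).
Polynomials up to degree 2 are differentiated exactly; for smooth signals
the interior error shrinks ∝ Δt². Endpoint frames are consequently the
least accurate; the synthetic round trips are unaffected because generator
and predictor share the stencils.

## Synthetic trials

The generators emulate the three study movements at 120 Hz (a typical IMU
motion-capture rate; the reference-force rate is kept equal to avoid
resampling inside tests):

- **Squat** (default: 0.4 m raised-cosine descent/ascent, 2 s cycle, two
  cycles, 1 s standing lead-in, feet planted 0.4 m apart): double support
  throughout; static COPs at (0, ±0.2, 0) give the truth GRFs equal and
  opposite lateral components.
- **Inline lunge** (squat with the left foot 0.4 m anterior, 0.2 m stance
  width): adds anterior GRF components of opposite sign between the feet;
  stride → 0 degenerates exactly to the squat.
- **Walking** (1.2 m/s, 0.65 m steps, 20% of each step period in double
  support, five steps): alternating phases; during stance the sole rolls
  heel-to-toe via smooth vertical ramps on the contact points (toes pitched
  up 0.06 m at touchdown, heel lifting 0.12 m before toe-off), so the COP
  model itself produces a forward-travelling COP; swing translates the foot
  two step lengths along a half-cosine with 0.08 m clearance and
  velocity-continuous touchdown.

Ground truth is constructed by running the *same* pivot decomposition the
solver uses, at a known true scale, on the clean kinematics. With two
independent directions the two-unknown least-squares solution is unique, so
round-trip recovery is a meaningful check of the pipeline's correctness and
of the identifiability of the scale — it is deliberately *not* evidence
about agreement with measured force plates, which adds soft tissue, shoe,
segment-parameter and sensor errors the generators do not model.

Two geometric choices make the generated truth satisfy exact force closure
(`GRF_L + GRF_R = F_COM` within 1e-9·BW, asserted at generation): the
squat/lunge stance is symmetric about the COM (horizontal COP offsets are
equal-opposite, so the purely-vertical-plus-symmetric resultant lies in the
span of the two pivot directions), and walking places both feet on the
progression line (zero step width) with the COM midway between the feet at
touchdown and only a 4 mm anterior modulation — small enough that the
resultant's tilt stays inside the cone of the two pivot directions for
every scale on the sweep grid (larger modulations make the rear-foot
magnitude go negative near toe-off for tall pivots, which would clamp and
break closure; the generator refuses to emit such truth). The smooth
contact ramps mean support labels switch a few frames before/after the
nominal touchdown/toe-off times — loading is gradual, as in real gait — so
phase-duration checks carry a few frames of tolerance.

Exported kinematics optionally carry seeded additive white Gaussian
position noise on the COM; the truth is always built from the clean signal,
and identical seeds reproduce trials bit-identically.

## Known limitations

- A single constant pivot height for all phases; evidence suggests it
  differs between single and double support and shifts with posture.
- No free vertical moment, no friction cone, no shoe-sole mechanics, no
  ground penetration dynamics.
- The 18-point layout is a versioned convention, not an anatomical fit.
- Walking truth requires the inline-stance geometry above; a laterally
  offset synthetic gait would need truth with non-zero closure residual.
- Endpoint frames use one-sided differentiation and are the least accurate
  on measured data.
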