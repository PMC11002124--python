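"""Synthetic trial generators: squat, inline lunge and walking.

Each generator builds a full kinematic trial — COM trajectory, per-foot
contact-point trajectories — and constructs ground-truth per-foot GRFs by
running the very pivot-point decomposition the solver uses, at a known true
VPPscale.  With two independent pivot directions the two-unknown
least-squares decomposition is unique, so recovering the truth from the
kinematics is a meaningful round-trip (this uniqueness, not independence of
code paths, is what the recovery tests certify; see docs/methods.md).

The stance geometries are chosen so that the resultant COM force lies exactly
in the span of the two pivot directions on every double-support frame
(symmetric lateral stance for squat/lunge, inline feet for walking); the
generated truth therefore satisfies force closure GRF_L + GRF_R = F_COM to
floating-point precision, which is asserted at generation time.

Exported kinematics may carry seeded additive Gaussian position noise; the
ground truth is always built from the clean signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact import (
    ContactParams,
    ContactPointSet,
    FLIGHT,
    classify_support,
    compute_cop,
    contact_weights,
    default_foot_layout,
)
from .errors import ValidationError
from .kinematics import SubjectParams, Trajectory, compute_com_force
from .solver import VppParams, predict_grf

#: Default subject: mass and height of a typical adult.
DEFAULT_SUBJECT = SubjectParams(M=75.0, BH=1.75)

DEFAULT_SAMPLE_RATE = 120.0  # Hz, typical IMU motion-capture rate

_COM_HEIGHT_FRACTION = 0.55  # standing COM height as a fraction of body height


@dataclass
class SyntheticTrial:
    """A generated trial with kinematics, labels and ground-truth forces.

    ``com`` is the exported COM trajectory (noisy when ``noise_sigma > 0``);
    ``com_clean`` is the noise-free signal the truth was built from.  After
    loading a trial from disk the two coincide (the clean signal is not
    persisted).
    """

    subject: SubjectParams
    kind: str
    sample_rate: float
    seed: int
    true_vppscale: float
    noise_sigma: float
    com: Trajectory
    com_clean: Trajectory
    contacts_l: ContactPointSet
    contacts_r: ContactPointSet
    truth_grf_l: np.ndarray
    truth_grf_r: np.ndarray
    truth_cop_l: np.ndarray
    truth_cop_r: np.ndarray
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.com.n


def validate_trial(trial: SyntheticTrial, tol_bw: float = 1e-9) -> None:
    """Assert the generated truth satisfies force closure on every frame.

    ``GRF_L + GRF_R = M·a_COM + M·g·ẑ`` within ``tol_bw``·BW (computed from
    the clean COM by the same Newton rule the pipeline uses).  Raises
    :class:`ValidationError` on violation.
    """
    f = compute_com_force(trial.com_clean, trial.subject)
    gap = np.linalg.norm(trial.truth_grf_l + trial.truth_grf_r - f.v, axis=1)
    grounded = trial.labels != FLIGHT
    worst = float(gap[grounded].max()) if np.any(grounded) else 0.0
    if worst > tol_bw * trial.subject.BW:
        raise ValidationError(
            f"ground-truth closure violated: max gap {worst:.3e} N "
            f"exceeds {tol_bw:.1e}·BW"
        )


def _assemble_trial(
    kind: str,
    subject: SubjectParams,
    t: np.ndarray,
    com_clean: np.ndarray,
    p_l: np.ndarray,
    p_r: np.ndarray,
    true_vppscale: float,
    noise_sigma: float,
    seed: int,
    contact_params: ContactParams,
    meta: dict,
) -> SyntheticTrial:
    """Run the forward pipeline on clean kinematics to build the truth."""
    cps_l = ContactPointSet(t, p_l)
    cps_r = ContactPointSet(t, p_r)
    fc_l = compute_cop(contact_weights(cps_l, contact_params), cps_l, contact_params)
    fc_r = compute_cop(contact_weights(cps_r, contact_params), cps_r, contact_params)
    labels = classify_support(fc_l, fc_r)

    com_traj = Trajectory(t, com_clean)
    f_com = compute_com_force(com_traj, subject)
    sol = predict_grf(
        f_com,
        com_traj,
        fc_l,
        fc_r,
        labels,
        VppParams(vppscale=true_vppscale),
        subject,
    )
    if np.any(sol.flags):
        raise ValidationError(
            "generator produced degenerate/ill-conditioned frames; "
            "check trial parameters"
        )

    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        com_export = com_clean + rng.normal(0.0, noise_sigma, com_clean.shape)
    else:
        com_export = com_clean.copy()

    trial = SyntheticTrial(
        subject=subject,
        kind=kind,
        sample_rate=1.0 / float(t[1] - t[0]),
        seed=seed,
        true_vppscale=true_vppscale,
        noise_sigma=noise_sigma,
        com=Trajectory(t, com_export),
        com_clean=com_traj,
        contacts_l=cps_l,
        contacts_r=cps_r,
        truth_grf_l=sol.grf_l,
        truth_grf_r=sol.grf_r,
        truth_cop_l=fc_l.cop.copy(),
        truth_cop_r=fc_r.cop.copy(),
        labels=labels,
        meta=meta,
    )
    validate_trial(trial)
    return trial


def _static_stance_trial(
    kind: str,
    subject: SubjectParams,
    depth: float,
    period: float,
    n_cycles: int,
    true_vppscale: float,
    noise_sigma: float,
    seed: int,
    sample_rate: float,
    stance_width: float,
    stride: float,
    lead_in: float,
    lead_out: float,
    foot_length: float,
    foot_width: float,
    contact_params: ContactParams,
) -> SyntheticTrial:
    """Shared squat/lunge builder: planted feet, raised-cosine COM descent."""
    if depth < 0:
        raise ValidationError(f"depth must be non-negative, got {depth}")
    if period <= 0:
        raise ValidationError(f"period must be positive, got {period}")
    if n_cycles < 1:
        raise ValidationError("need at least one movement cycle")
    z0 = _COM_HEIGHT_FRACTION * subject.BH
    if z0 - depth <= 0:
        raise ValidationError(
            f"depth {depth} m would push the COM below the ground "
            f"(standing COM height {z0:.3f} m)"
        )

    dt = 1.0 / sample_rate
    duration = lead_in + n_cycles * period + lead_out
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) * dt

    # raised-cosine descent/ascent, flat during lead-in/out
    phase = np.clip((t - lead_in) / period, 0.0, float(n_cycles))
    z = z0 - 0.5 * depth * (1.0 - np.cos(2.0 * np.pi * phase))
    com = np.zeros((n, 3))
    com[:, 2] = z

    # planted feet; COPs land at (±stride/2, ±stance_width/2, 0)
    lay_l = default_foot_layout(foot_length, foot_width, "left")
    lay_r = default_foot_layout(foot_length, foot_width, "right")
    cx = lay_r[:, 0].mean()
    origin_l = np.array([stride / 2.0 - cx, stance_width / 2.0, 0.0])
    origin_r = np.array([-stride / 2.0 - cx, -stance_width / 2.0, 0.0])
    p_l = np.broadcast_to(lay_l + origin_l, (n, lay_l.shape[0], 3)).copy()
    p_r = np.broadcast_to(lay_r + origin_r, (n, lay_r.shape[0], 3)).copy()

    meta = {
        "depth": depth,
        "period": period,
        "n_cycles": n_cycles,
        "stance_width": stance_width,
        "stride": stride,
        "lead_in": lead_in,
        "lead_out": lead_out,
        "descent_onset_time": lead_in,
        "foot_length": foot_length,
        "foot_width": foot_width,
    }
    return _assemble_trial(
        kind, subject, t, com, p_l, p_r, true_vppscale, noise_sigma, seed,
        contact_params, meta,
    )


def simulate_squat(
    subject: SubjectParams = DEFAULT_SUBJECT,
    depth: float = 0.4,
    period: float = 2.0,
    n_cycles: int = 2,
    true_vppscale: float = 0.9,
    noise_sigma: float = 0.0,
    seed: int = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    stance_width: float = 0.4,
    lead_in: float = 1.0,
    lead_out: float = 0.5,
    foot_length: float = 0.25,
    foot_width: float = 0.10,
    contact_params: ContactParams = ContactParams(),
) -> SyntheticTrial:
    """Squat trial: double support throughout, COM descending then ascending.

    The COM follows a raised-cosine vertical excursion of the given ``depth``
    (m) and ``period`` (s) per cycle, after a standing ``lead_in``.  Feet are
    planted symmetrically ``stance_width`` apart, so the static COPs sit at
    (0, ±stance_width/2, 0) and the truth GRFs carry equal-opposite lateral
    components — the signature the pivot-point decomposition reproduces and a
    COM-only split cannot.
    """
    return _static_stance_trial(
        "squat", subject, depth, period, n_cycles, true_vppscale, noise_sigma,
        seed, sample_rate, stance_width, 0.0, lead_in, lead_out,
        foot_length, foot_width, contact_params,
    )


def simulate_lunge(
    subject: SubjectParams = DEFAULT_SUBJECT,
    stride: float = 0.4,
    depth: float = 0.3,
    period: float = 2.0,
    n_cycles: int = 2,
    true_vppscale: float = 0.9,
    noise_sigma: float = 0.0,
    seed: int = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    stance_width: float = 0.2,
    lead_in: float = 1.0,
    lead_out: float = 0.5,
    foot_length: float = 0.25,
    foot_width: float = 0.10,
    contact_params: ContactParams = ContactParams(),
) -> SyntheticTrial:
    """Inline-lunge trial: split stance (left foot ``stride`` m anterior).

    Same COM excursion as the squat, but the anterior-posterior foot offset
    gives the two truth GRFs anterior components of opposite sign whenever
    the pivot point lies between the COPs.  ``stride = 0`` degenerates to a
    squat with the same remaining parameters.
    """
    return _static_stance_trial(
        "lunge", subject, depth, period, n_cycles, true_vppscale, noise_sigma,
        seed, sample_rate, stance_width, stride, lead_in, lead_out,
        foot_length, foot_width, contact_params,
    )


def _smooth01(u: np.ndarray) -> np.ndarray:
    """Cosine-smoothed ramp from 0 to 1 on u ∈ [0, 1], clamped outside."""
    u = np.clip(u, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def _walk_foot_positions(
    t: np.ndarray,
    contact_times: np.ndarray,
    contact_x: np.ndarray,
    layout: np.ndarray,
    y_offset: float,
    step_length: float,
    step_period: float,
    ds_fraction: float,
    z_toe_down: float,
    z_heel_lift: float,
    swing_height: float,
    foot_length: float,
) -> np.ndarray:
    """Contact-point positions for one foot over the walk timeline.

    Stance lasts (1+ds)·T from each contact; the sole rolls heel-to-toe via
    vertical ramps (toes pitched up at touchdown, heel lifting before
    toe-off), which makes the weighted COP travel forward.  Swing translates
    the flat foot two step lengths along a half-cosine with a sinusoidal
    vertical clearance; its velocity vanishes at touchdown so contact
    re-engages smoothly.
    """
    n = t.size
    n_cp = layout.shape[0]
    t_stance = (1.0 + ds_fraction) * step_period
    t_swing = (1.0 - ds_fraction) * step_period
    cx = layout[:, 0].mean()
    x_frac = layout[:, 0] / foot_length

    p = np.empty((n, n_cp, 3))
    p[:, :, 1] = y_offset + layout[:, 1]

    for i, ti in enumerate(t):
        j = int(np.searchsorted(contact_times, ti, side="right")) - 1
        if j >= 0 and ti < contact_times[j] + t_stance:
            s = (ti - contact_times[j]) / t_stance
            z_toe = z_toe_down * (1.0 - _smooth01(s / 0.2))
            z_heel = z_heel_lift * _smooth01((s - 0.7) / 0.3)
            p[i, :, 0] = contact_x[j] - cx + layout[:, 0]
            p[i, :, 2] = z_toe * x_frac + z_heel * (1.0 - x_frac)
        else:
            if j < 0:
                x_from = contact_x[0] - 2.0 * step_length
                t_off = contact_times[0] - t_swing
            else:
                x_from = contact_x[j]
                t_off = contact_times[j] + t_stance
            tau = np.clip((ti - t_off) / t_swing, 0.0, 1.0)
            advance = 2.0 * step_length * 0.5 * (1.0 - np.cos(np.pi * tau))
            p[i, :, 0] = x_from + advance - cx + layout[:, 0]
            # pitch blends: keep the heel lifted just after toe-off and pitch
            # the toes up before touchdown so z is continuous across phases
            z_off = z_heel_lift * (1.0 - x_frac) * (1.0 - _smooth01(tau / 0.3))
            z_td = z_toe_down * x_frac * _smooth01((tau - 0.7) / 0.3)
            p[i, :, 2] = swing_height * np.sin(np.pi * tau) + z_off + z_td
    return p


def simulate_walk(
    subject: SubjectParams = DEFAULT_SUBJECT,
    speed: float = 1.2,
    step_length: float = 0.65,
    ds_fraction: float = 0.2,
    true_vppscale: float = 0.9,
    noise_sigma: float = 0.0,
    seed: int = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    step_width: float = 0.0,
    n_steps: int = 5,
    foot_length: float = 0.25,
    foot_width: float = 0.10,
    contact_params: ContactParams = ContactParams(),
) -> SyntheticTrial:
    """Walking trial: alternating single/double support over several steps.

    ``ds_fraction`` is the fraction of each step period spent in double
    support (each stance lasts (1+ds)·T from touchdown, T = step period).
    The default ``step_width = 0`` places both feet on the progression line;
    this keeps the resultant COM force exactly in the plane spanned by the
    two pivot directions during double support, so the generated truth closes
    exactly (see module docstring).  The COM advances at ``speed`` with small
    per-step anterior and vertical oscillations.
    """
    if not (0.0 < ds_fraction < 0.5):
        raise ValidationError(f"ds_fraction must be in (0, 0.5), got {ds_fraction}")
    if speed <= 0 or step_length <= 0:
        raise ValidationError("speed and step_length must be positive")
    if n_steps < 3:
        raise ValidationError("need at least 3 steps for a double step")

    T = step_length / speed
    t0 = 0.25 * T  # first (left) touchdown; right foot mid-stance at t = 0
    duration = t0 + (n_steps - 1) * T + 0.5 * T
    dt = 1.0 / sample_rate
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) * dt

    # contact schedule: right foot has a pre-trial contact at t0 - T
    left_ks = np.arange(0, n_steps, 2)
    right_ks = np.arange(-1, n_steps, 2)
    tc_l = t0 + left_ks * T
    tc_r = t0 + right_ks * T
    x_l = left_ks * step_length
    x_r = right_ks * step_length

    lay_l = default_foot_layout(foot_length, foot_width, "left")
    lay_r = default_foot_layout(foot_length, foot_width, "right")
    common = dict(
        step_length=step_length,
        step_period=T,
        ds_fraction=ds_fraction,
        z_toe_down=0.06,
        z_heel_lift=0.12,
        swing_height=0.08,
        foot_length=foot_length,
    )
    p_l = _walk_foot_positions(t, tc_l, x_l, lay_l, +step_width / 2.0, **common)
    p_r = _walk_foot_positions(t, tc_r, x_r, lay_r, -step_width / 2.0, **common)

    z0 = _COM_HEIGHT_FRACTION * subject.BH
    com = np.zeros((n, 3))
    # at each touchdown the COM sits roughly midway between the feet; the
    # anterior modulation is kept small enough that the force tilt stays
    # inside the cone spanned by the two pivot directions for scales up to 2
    com[:, 0] = (
        speed * (t - t0)
        - step_length / 2.0
        + 0.004 * np.sin(2.0 * np.pi * (t - t0) / T)
    )
    com[:, 2] = z0 - 0.02 * np.cos(2.0 * np.pi * (t - t0) / T)

    meta = {
        "speed": speed,
        "step_length": step_length,
        "step_period": T,
        "ds_fraction": ds_fraction,
        "step_width": step_width,
        "n_steps": n_steps,
        "first_touchdown_time": t0,
        "left_contact_times": tc_l.tolist(),
        "right_contact_times": tc_r.tolist(),
        "foot_length": foot_length,
        "foot_width": foot_width,
    }
    return _assemble_trial(
        "walking", subject, t, com, p_l, p_r, true_vppscale, noise_sigma,
        seed, contact_params, meta,
    )


_SIMULATORS = {
    "squat": simulate_squat,
    "lunge": simulate_lunge,
    "walk": simulate_walk,
    "walking": simulate_walk,
}


def simulate(kind: str, **kwargs) -> SyntheticTrial:
    """Dispatch to a generator by trial kind ('squat', 'lunge', 'walk')."""
    try:
        fn = _SIMULATORS[kind]
    except KeyError:
        raise ValidationError(
            f"unknown trial kind {kind!r}; expected one of {sorted(set(_SIMULATORS))}"
        ) from None
    return fn(**kwargs)
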