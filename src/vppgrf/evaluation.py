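"""Trial segmentation, BW-normalised RMSE and the VPPscale sweep.

The pivot height scale is swept over a grid (0.2 to 2.0 in steps of 0.1 by
default), the per-foot GRF prediction is rerun at each value, and the
root-mean-square error against reference forces — measured or synthetic
ground truth — is reported per direction (anterior x, lateral y, vertical z)
in units of body weight.  Errors pool both feet: the RMSE in direction d is
sqrt(mean over frames and feet of (pred_d - ref_d)^2) / BW.

The optimum scale across a collection of trials is a reproducible stand-in
for by-eye selection: the grid point minimising the median (across trials)
of the summed directional RMSE, ties broken toward the smaller scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contact import DOUBLE, SINGLE_L, classify_support, compute_cop, contact_weights
from .errors import SegmentationError, ValidationError
from .kinematics import SubjectParams, Trajectory, compute_com_force, first_derivative
from .solver import VppParams, predict_grf

#: The standard sweep grid: 0.2 to 2.0 inclusive in increments of 0.1.
DEFAULT_GRID = np.round(np.linspace(0.2, 2.0, 19), 10)

DIRECTIONS = ("anterior", "lateral", "vertical")


@dataclass
class SweepResult:
    """Per-direction RMSE (BW) over a grid of VPPscale values for one trial."""

    scales: np.ndarray  # (k,)
    rmse: np.ndarray  # (k, 3) in BW units, columns (anterior, lateral, vertical)
    trial_kind: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.rmse = np.asarray(self.rmse, dtype=float)
        if self.scales.ndim != 1 or self.rmse.shape != (self.scales.size, 3):
            raise ValidationError("rmse must have shape (len(scales), 3)")
        if self.scales.size == 0:
            raise ValidationError("empty sweep grid")
        if np.any(np.diff(self.scales) <= 0):
            raise ValidationError("sweep grid must be strictly increasing")

    @property
    def total(self) -> np.ndarray:
        """Summed directional RMSE per grid point."""
        return self.rmse.sum(axis=1)

    @property
    def optimum(self) -> float:
        """Grid point minimising this trial's summed RMSE (first on ties)."""
        return float(self.scales[int(np.argmin(self.total))])


@dataclass(frozen=True)
class MovementSegment:
    """A detected analysis window [start, end] (inclusive frame indices)."""

    kind: str
    start: int
    end: int
    rule: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"invalid segment [{self.start}, {self.end}]")


def rmse_by_direction(
    pred_l: np.ndarray,
    pred_r: np.ndarray,
    ref_l: np.ndarray,
    ref_r: np.ndarray,
    subject: SubjectParams,
) -> np.ndarray:
    """Per-direction RMSE in body-weight units, pooling both feet.

    All inputs are ``(n, 3)`` force arrays in N.  Returns a 3-vector in the
    order (anterior, lateral, vertical).
    """
    arrs = [np.asarray(a, dtype=float) for a in (pred_l, pred_r, ref_l, ref_r)]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs) or shape[-1] != 3:
        raise ValidationError("prediction/reference GRF arrays must share shape (n, 3)")
    err = np.concatenate([arrs[0] - arrs[2], arrs[1] - arrs[3]], axis=0)
    return np.sqrt(np.mean(err**2, axis=0)) / subject.BW


def prepare_trial(trial, contact_params=None, com_cutoff_hz: float | None = None):
    """Scale-independent half of the pipeline for a trial.

    Runs the contact model (weights, COPs, support labels) on the trial's
    contact points and computes the resultant COM force from its exported
    COM, optionally zero-phase low-pass filtering the COM first (essential
    for noisy kinematics; a cutoff of about six times the movement's
    fundamental frequency works well).  Returns
    ``(com, f_com, fc_l, fc_r, labels)``.
    """
    from .contact import ContactParams

    cp = contact_params if contact_params is not None else ContactParams()
    fc_l = compute_cop(contact_weights(trial.contacts_l, cp), trial.contacts_l, cp)
    fc_r = compute_cop(contact_weights(trial.contacts_r, cp), trial.contacts_r, cp)
    labels = classify_support(fc_l, fc_r)
    com = trial.com
    if com_cutoff_hz is not None:
        com = com.smoothed(com_cutoff_hz)
    f_com = compute_com_force(com, trial.subject)
    return com, f_com, fc_l, fc_r, labels


def predict_for_trial(
    trial,
    vpp_params: VppParams = VppParams(),
    contact_params=None,
    com_cutoff_hz: float | None = None,
):
    """Full per-foot GRF prediction for a trial object; returns a VppSolution."""
    com, f_com, fc_l, fc_r, labels = prepare_trial(trial, contact_params, com_cutoff_hz)
    return predict_grf(f_com, com, fc_l, fc_r, labels, vpp_params, trial.subject)


def sweep_vppscale(
    trial,
    grid: np.ndarray | None = None,
    vpp_params: VppParams = VppParams(),
    contact_params=None,
    com_cutoff_hz: float | None = None,
    trial_id: str = "",
) -> SweepResult:
    """Run the prediction pipeline at every grid value and score it.

    ``trial`` provides kinematics (``com``, ``contacts_l/r``), the subject,
    and reference per-foot GRFs (``truth_grf_l/r``) — a
    :class:`~vppgrf.synthetic.SyntheticTrial` or any object with those
    attributes.  The contact model and the COM force are computed once (they
    do not depend on the scale); see :func:`prepare_trial` for the
    ``com_cutoff_hz`` smoothing option.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty sweep grid")

    com, f_com, fc_l, fc_r, labels = prepare_trial(trial, contact_params, com_cutoff_hz)

    rmse = np.empty((grid.size, 3))
    for i, s in enumerate(grid):
        params = VppParams(
            vppscale=float(s),
            eps_fz=vpp_params.eps_fz,
            nonneg_policy=vpp_params.nonneg_policy,
            cond_limit=vpp_params.cond_limit,
        )
        sol = predict_grf(f_com, com, fc_l, fc_r, labels, params, trial.subject)
        rmse[i] = rmse_by_direction(
            sol.grf_l, sol.grf_r, trial.truth_grf_l, trial.truth_grf_r, trial.subject
        )
    return SweepResult(scales=grid, rmse=rmse, trial_kind=trial.kind, trial_id=trial_id)


def select_optimal_scale(results: Sequence[SweepResult]) -> float:
    """Optimal scale across trials: argmin of the median summed RMSE.

    All results must share the same grid.  Exact ties go to the smaller
    scale.
    """
    results = list(results)
    if not results:
        raise ValidationError("no sweep results to aggregate")
    grid = results[0].scales
    for r in results[1:]:
        if r.scales.shape != grid.shape or not np.array_equal(r.scales, grid):
            raise ValidationError("sweep results are not on a shared grid")
    totals = np.stack([r.total for r in results], axis=1)  # (k, n_trials)
    med = np.median(totals, axis=1)
    return float(grid[int(np.argmin(med))])


def segment_trial(
    kind: str,
    com: Trajectory,
    labels: np.ndarray | None = None,
    v_thresh: float = 0.02,
    smooth_cutoff_hz: float | None = 6.0,
) -> MovementSegment:
    """Locate the analysis window of a trial.

    Squat/lunge: from the first frame where the (smoothed) COM vertical
    velocity drops below ``-v_thresh`` m/s to the last frame where it exceeds
    ``+v_thresh`` — the descent-to-ascent excursion.  Walking: from the first
    left-foot touchdown (rising edge of left contact in ``labels``) through
    the frame before the next left touchdown — one double step.
    """
    if kind in ("squat", "lunge"):
        z = com.v[:, 2:3]
        if smooth_cutoff_hz is not None and smooth_cutoff_hz < com.sample_rate / 2:
            com_s = com.smoothed(smooth_cutoff_hz)
            z = com_s.v[:, 2:3]
        vz = first_derivative(z, com.dt)[:, 0]
        down = np.flatnonzero(vz < -v_thresh)
        up = np.flatnonzero(vz > v_thresh)
        if down.size == 0 or up.size == 0 or up[-1] <= down[0]:
            raise SegmentationError(
                f"no descent/ascent excursion found (threshold {v_thresh} m/s)"
            )
        return MovementSegment(kind, int(down[0]), int(up[-1]), "com_vertical_velocity")
    if kind in ("walk", "walking"):
        if labels is None:
            raise ValidationError("walking segmentation requires support labels")
        labels = np.asarray(labels)
        active = (labels == DOUBLE) | (labels == SINGLE_L)
        onsets = np.flatnonzero(active[1:] & ~active[:-1]) + 1
        if onsets.size < 2:
            raise SegmentationError("fewer than two left-foot touchdowns in trial")
        return MovementSegment("walking", int(onsets[0]), int(onsets[1]) - 1, "left_foot_contacts")
    raise ValidationError(f"unknown trial kind {kind!r}")


def plot_sweep(results: Sequence[SweepResult], path=None):
    """Simple RMSE-vs-scale figure (one panel per direction); optional save.

    Requires matplotlib (``pip install vppgrf[plot]``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = list(results)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for j, (ax, name) in enumerate(zip(axes, DIRECTIONS)):
        for r in results:
            ax.plot(r.scales, r.rmse[:, j], alpha=0.7, label=r.trial_id or r.trial_kind)
        ax.set_title(name)
        ax.set_xlabel("VPPscale")
        ax.set_ylabel("RMSE (BW)")
    if results:
        axes[0].legend(fontsize="small")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
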