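"""Foot–ground contact model: per-point weights, COP and support phase.

Each foot carries a fixed set of contact points (18 by default).  A point
contributes to ground contact with a weight that fades smoothly to zero as it
lifts off the ground or moves horizontally — the product of a position and a
velocity transition function, each a clamped raised-cosine ramp:

    WP(z)  = 1                         for z   <= 0.8 * z_lim
           = 0.5*(cos(pi*(z/z_lim - 0.8)/0.2) + 1)    in between
           = 0                         for z   >= z_lim
    WV(vh) = 1                         for v_h <= 0.15 * v_lim
           = 0.5*(cos(pi*(v_h/v_lim - 0.15)/0.85) + 1) in between
           = 0                         for v_h >= v_lim

with z_lim = 0.04 m and v_lim = 1.3 m/s by default.  The foot's centre of
pressure is the weight-weighted mean of its contact-point positions,
projected onto the ground plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .errors import ValidationError
from .kinematics import first_derivative

DEFAULT_N_CONTACT_POINTS = 18

#: Support-phase labels
DOUBLE = "double"
SINGLE_L = "single_L"
SINGLE_R = "single_R"
FLIGHT = "flight"


@dataclass(frozen=True)
class ContactParams:
    """Transition limits of the contact model.

    z_lim : vertical position limit in m (full contact below 0.8·z_lim).
    v_lim : horizontal speed limit in m/s (full contact below 0.15·v_lim).
    w_support_threshold : minimum total weight for a foot to count as grounded.
    """

    z_lim: float = 0.04
    v_lim: float = 1.3
    w_support_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (self.z_lim > 0):
            raise ValidationError(f"z_lim must be positive, got {self.z_lim}")
        if not (self.v_lim > 0):
            raise ValidationError(f"v_lim must be positive, got {self.v_lim}")
        if not (self.w_support_threshold > 0):
            raise ValidationError("w_support_threshold must be positive")


@dataclass
class ContactPointSet:
    """Contact-point position time series for one foot.

    ``p`` has shape ``(n_frames, n_cp, 3)`` in metres, on the shared uniform
    time base ``t``.  Point velocities are finite differences of positions
    (central, second-order one-sided at the endpoints).
    """

    t: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.ascontiguousarray(self.t, dtype=float)
        self.p = np.ascontiguousarray(self.p, dtype=float)
        if self.p.ndim != 3 or self.p.shape[0] != self.t.size or self.p.shape[2] != 3:
            raise ValidationError(
                f"contact positions must have shape (n_frames, n_cp, 3), got {self.p.shape}"
            )
        if self.p.shape[1] < 1:
            raise ValidationError("need at least one contact point")
        if not np.all(np.isfinite(self.p)):
            raise ValidationError("contact positions contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def n_cp(self) -> int:
        return self.p.shape[1]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @cached_property
    def velocity(self) -> np.ndarray:
        """Point velocities, shape (n_frames, n_cp, 3)."""
        return first_derivative(self.p, self.dt)

    @cached_property
    def horizontal_speed(self) -> np.ndarray:
        """‖v(x, y)‖ per point, shape (n_frames, n_cp)."""
        return np.linalg.norm(self.velocity[:, :, :2], axis=2)


@dataclass
class FootContact:
    """Per-frame contact state of one foot.

    ``cop`` rows are NaN where the foot is airborne (``defined`` False).
    """

    weights: np.ndarray  # (n, n_cp)
    w_total: np.ndarray  # (n,)
    cop: np.ndarray  # (n, 3)
    defined: np.ndarray  # (n,) bool


def _raised_cosine(u: np.ndarray, lo: float) -> np.ndarray:
    """Clamped raised-cosine ramp: 1 for u <= lo, 0 for u >= 1, smooth between.

    ``u`` is the argument normalised by its limit.
    """
    u = np.asarray(u, dtype=float)
    w = 0.5 * (np.cos(np.pi * (u - lo) / (1.0 - lo)) + 1.0)
    return np.where(u <= lo, 1.0, np.where(u >= 1.0, 0.0, w))


def position_weight(z, params: ContactParams = ContactParams()):
    """Position transition weight WP(z) ∈ [0, 1] (vectorised)."""
    return _raised_cosine(np.asarray(z, dtype=float) / params.z_lim, 0.8)


def velocity_weight(v_h, params: ContactParams = ContactParams()):
    """Velocity transition weight WV(v_h) ∈ [0, 1] for horizontal speed v_h ≥ 0."""
    return _raised_cosine(np.asarray(v_h, dtype=float) / params.v_lim, 0.15)


def contact_weights(cps: ContactPointSet, params: ContactParams = ContactParams()) -> np.ndarray:
    """Per-point contact weights W_i = WP(z_i)·WV(‖v_i(x,y)‖), shape (n, n_cp)."""
    wp = position_weight(cps.p[:, :, 2], params)
    wv = velocity_weight(cps.horizontal_speed, params)
    return wp * wv


def compute_cop(
    weights: np.ndarray,
    cps: ContactPointSet,
    params: ContactParams = ContactParams(),
    project_to_ground: bool = True,
) -> FootContact:
    """Centre of pressure as the weighted mean of contact-point positions.

    Frames whose total weight falls below ``params.w_support_threshold`` are
    flagged undefined (NaN COP) rather than raising on the 0/0 mean; the
    downstream solver treats such a foot as airborne.  By default the COP is
    projected onto the ground plane z = 0 (a centre of pressure lives on the
    contact surface); pass ``project_to_ground=False`` for the raw mean.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (cps.n_frames, cps.n_cp):
        raise ValidationError(
            f"weights shape {weights.shape} does not match contact set "
            f"({cps.n_frames}, {cps.n_cp})"
        )
    w_total = weights.sum(axis=1)
    defined = w_total >= params.w_support_threshold
    cop = np.full((cps.n_frames, 3), np.nan)
    if np.any(defined):
        num = np.einsum("ni,nij->nj", weights[defined], cps.p[defined])
        cop[defined] = num / w_total[defined, None]
        if project_to_ground:
            cop[defined, 2] = 0.0
    return FootContact(weights=weights, w_total=w_total, cop=cop, defined=defined)


def classify_support(left: FootContact, right: FootContact) -> np.ndarray:
    """Per-frame support label: double / single_L / single_R / flight."""
    if left.defined.shape != right.defined.shape:
        raise ValidationError("left/right contact sequences have different lengths")
    labels = np.full(left.defined.shape, FLIGHT, dtype="<U8")
    labels[left.defined & right.defined] = DOUBLE
    labels[left.defined & ~right.defined] = SINGLE_L
    labels[~left.defined & right.defined] = SINGLE_R
    return labels


def default_foot_layout(
    foot_length: float, foot_width: float, side: str = "right"
) -> np.ndarray:
    """Deterministic 18-point sole grid in foot-local coordinates (layout v1).

    Local frame: x from heel (0) to toe (foot_length), y across the sole in
    [-foot_width/2, +foot_width/2], z = 0.  Rows: 2 heel, 4 midfoot,
    8 forefoot (two rows of 4), 4 toe.  The left layout mirrors the right
    across y.
    """
    if foot_length <= 0 or foot_width <= 0:
        raise ValidationError("foot dimensions must be positive")
    L, W = foot_length, foot_width
    rows = [
        (0.05, (-0.20, 0.20)),
        (0.40, (-0.45, -0.15, 0.15, 0.45)),
        (0.65, (-0.45, -0.15, 0.15, 0.45)),
        (0.78, (-0.45, -0.15, 0.15, 0.45)),
        (0.95, (-0.35, -0.12, 0.12, 0.35)),
    ]
    pts = np.array(
        [(xf * L, yf * W, 0.0) for xf, ys in rows for yf in ys], dtype=float
    )
    assert pts.shape == (DEFAULT_N_CONTACT_POINTS, 3)
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    if side == "left":
        pts[:, 1] *= -1.0
    return pts
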