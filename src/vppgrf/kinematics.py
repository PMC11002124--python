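"""Whole-body centre-of-mass kinematics and the resultant COM force.

The Newton equation for the whole body states that the sum of all external
forces equals body mass times the COM acceleration.  When ground contact is
the only external contact force, the resultant COM force

    F_COM(t) = M * a_COM(t) + M * g * z_hat

equals the total ground reaction force (the static weight term is included so
that quiet standing yields F_COM = body weight, not zero).

Coordinate convention (used everywhere in this package): right-handed lab
frame, x anterior, y left-lateral, z vertical up, ground plane at z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .filters import lowpass

DEFAULT_GRAVITY = 9.81  # m/s^2

_UNIFORM_DT_TOL = 1e-9  # s


@dataclass(frozen=True)
class SubjectParams:
    """Anthropometric parameters of one subject.

    Attributes
    ----------
    M : float
        Total body mass in kg.
    BH : float
        Body height in m.
    g_mag : float
        Gravitational acceleration magnitude in m/s².
    """

    M: float
    BH: float
    g_mag: float = DEFAULT_GRAVITY

    def __post_init__(self) -> None:
        if not (self.M > 0):
            raise ValidationError(f"body mass must be positive, got {self.M}")
        if not (self.BH > 0):
            raise ValidationError(f"body height must be positive, got {self.BH}")
        if not (self.g_mag > 0):
            raise ValidationError(f"gravity magnitude must be positive, got {self.g_mag}")

    @property
    def BW(self) -> float:
        """Body weight M·g in N."""
        return self.M * self.g_mag


@dataclass
class Trajectory:
    """A uniformly sampled 3-vector time series in the lab frame.

    ``v`` has shape ``(n, 3)``; units depend on context (m, m/s or N).
    """

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.ascontiguousarray(self.t, dtype=float)
        self.v = np.ascontiguousarray(self.v, dtype=float)
        if self.t.ndim != 1:
            raise ValidationError("time must be a 1-D array")
        if self.v.shape != (self.t.size, 3):
            raise ValidationError(
                f"values must have shape ({self.t.size}, 3), got {self.v.shape}"
            )
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.v)):
            raise ValidationError("trajectory contains non-finite values")
        if self.t.size >= 2:
            dts = np.diff(self.t)
            if dts[0] <= 0 or np.max(np.abs(dts - dts[0])) > _UNIFORM_DT_TOL:
                raise ValidationError("time stamps are not uniformly increasing")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            raise ValidationError("trajectory has fewer than 2 samples; dt undefined")
        return float(self.t[1] - self.t[0])

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    def with_values(self, v: np.ndarray) -> "Trajectory":
        """A new trajectory sharing this time base."""
        return Trajectory(self.t.copy(), np.asarray(v, dtype=float))

    def smoothed(self, cutoff_hz: float, order: int = 2) -> "Trajectory":
        """Zero-phase low-pass filtered copy."""
        return self.with_values(lowpass(self.v, cutoff_hz, self.sample_rate, order=order))


@dataclass
class SegmentSet:
    """Body segments with mass fractions and segment-COM trajectories.

    Mass fractions are dimensionless shares of total body mass and must sum
    to 1; all segment trajectories must share the same time base.
    """

    names: tuple
    mass_fractions: np.ndarray
    trajectories: tuple
    sample_rate: float = field(init=False)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.mass_fractions = np.asarray(self.mass_fractions, dtype=float)
        self.trajectories = tuple(self.trajectories)
        k = len(self.names)
        if not (k == self.mass_fractions.size == len(self.trajectories)):
            raise ValidationError("names, mass_fractions and trajectories must align")
        if k == 0:
            raise ValidationError("segment set is empty")
        s = float(self.mass_fractions.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValidationError(f"mass fractions must sum to 1, got {s!r}")
        t0 = self.trajectories[0].t
        for name, tr in zip(self.names, self.trajectories):
            if tr.n != t0.size:
                raise ValidationError(f"segment {name!r}: trajectory length mismatch")
            if np.max(np.abs(tr.t - t0)) > _UNIFORM_DT_TOL:
                raise ValidationError(f"segment {name!r}: time base mismatch")
        self.sample_rate = self.trajectories[0].sample_rate


def first_derivative(v: np.ndarray, dt: float) -> np.ndarray:
    """Second-order finite-difference first derivative along axis 0.

    Central differences at interior samples, one-sided second-order stencils
    at the endpoints (first-order if only 2 samples are available).
    """
    v = np.asarray(v, dtype=float)
    n = v.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples to differentiate")
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) / (2.0 * dt)
    if n >= 3:
        d[0] = (-3.0 * v[0] + 4.0 * v[1] - v[2]) / (2.0 * dt)
        d[-1] = (3.0 * v[-1] - 4.0 * v[-2] + v[-3]) / (2.0 * dt)
    else:
        d[0] = d[-1] = (v[1] - v[0]) / dt
    return d


def second_derivative(v: np.ndarray, dt: float) -> np.ndarray:
    """Second-order finite-difference second derivative along axis 0.

    Central three-point stencil at interior samples; one-sided second-order
    four-point stencils at the endpoints (falls back to the adjacent interior
    value when only 3 samples exist).
    """
    v = np.asarray(v, dtype=float)
    n = v.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 samples for a second derivative")
    a = np.empty_like(v)
    a[1:-1] = (v[2:] - 2.0 * v[1:-1] + v[:-2]) / dt**2
    if n >= 4:
        a[0] = (2.0 * v[0] - 5.0 * v[1] + 4.0 * v[2] - v[3]) / dt**2
        a[-1] = (2.0 * v[-1] - 5.0 * v[-2] + 4.0 * v[-3] - v[-4]) / dt**2
    else:
        a[0] = a[1]
        a[-1] = a[-2]
    return a


def compute_com(segments: SegmentSet, params: SubjectParams | None = None) -> Trajectory:
    """Whole-body COM trajectory as the mass-fraction-weighted mean of segment COMs."""
    stack = np.stack([tr.v for tr in segments.trajectories], axis=0)  # (k, n, 3)
    w = segments.mass_fractions[:, None, None]
    com = (w * stack).sum(axis=0)
    return Trajectory(segments.trajectories[0].t.copy(), com)


def compute_com_force(
    com: Trajectory,
    params: SubjectParams,
    smooth_cutoff_hz: float | None = None,
) -> Trajectory:
    """Resultant COM force F_COM = M·a_COM + M·g·ẑ from the COM position.

    The acceleration is obtained by finite differences (see
    :func:`second_derivative`).  With ``smooth_cutoff_hz`` set, the position is
    zero-phase low-pass filtered before differentiation — recommended for
    noisy measured or synthetic kinematics.
    """
    if com.n < 3:
        raise ValidationError("COM trajectory needs at least 3 samples")
    pos = com.v
    if smooth_cutoff_hz is not None:
        pos = lowpass(pos, smooth_cutoff_hz, com.sample_rate)
    a = second_derivative(pos, com.dt)
    f = params.M * a
    f[:, 2] += params.M * params.g_mag
    return com.with_values(f)
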