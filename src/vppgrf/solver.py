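"""Virtual pivot point force decomposition.

During double support, the two per-foot ground reaction forces are assumed to
point from each foot's centre of pressure towards a common virtual pivot
point (VPP) above the centre of mass:

    VPP(x, y) = COM(x, y) + COM(z)/F_COM(z) * F_COM(x, y)
    VPP(z)    = VPPscale * BH

With unit virtual pivot vectors VPV_{L/R} = (VPP - COP_{L/R}) / ‖·‖, force
closure F_COM = a·VPV_L + b·VPV_R is a 3-equation, 2-unknown linear system,
solved in the minimum-residual least-squares sense for the scalar magnitudes
(a, b).  During single support the whole resultant COM force acts at the
stance foot's COP; in flight both GRFs are zero.

Because unilateral contact cannot pull a foot into the ground, a negative
least-squares magnitude is, by default, clamped to zero and the other foot
refit as the 1-D projection of F_COM onto its direction
(``nonneg_policy="clamp_reassign"``); ``"allow_negative"`` keeps the raw
solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact import DOUBLE, SINGLE_L, SINGLE_R, FootContact
from .errors import IllConditionedError, ValidationError
from .kinematics import SubjectParams, Trajectory

# Per-frame diagnostic flags (bitmask)
FLAG_DEGENERATE_FZ = 1  # |F_COM(z)| below eps_fz; VPP xy fell back to COM xy
FLAG_ILL_CONDITIONED = 2  # VPVs near-parallel; 50/50 mean-direction fallback
FLAG_CLAMPED = 4  # a negative magnitude was clamped and the other foot refit

FLAG_NAMES = {
    FLAG_DEGENERATE_FZ: "degenerate_fz",
    FLAG_ILL_CONDITIONED: "ill_conditioned",
    FLAG_CLAMPED: "clamped",
}


def flags_to_str(flag: int) -> str:
    """Human-readable rendering of a per-frame flag bitmask."""
    names = [name for bit, name in FLAG_NAMES.items() if flag & bit]
    return "|".join(names)


@dataclass(frozen=True)
class VppParams:
    """Solver parameters.

    vppscale : VPP height as a fraction of body height (dimensionless).
    eps_fz : minimum |F_COM(z)| in N for the planar VPP placement; ``None``
        means 1e-6·BW of the subject.
    nonneg_policy : "clamp_reassign" (default) or "allow_negative".
    cond_limit : maximum condition number of the 3×2 direction matrix before
        the frame is declared ill-conditioned.
    """

    vppscale: float = 0.9
    eps_fz: float | None = None
    nonneg_policy: str = "clamp_reassign"
    cond_limit: float = 1e8

    def __post_init__(self) -> None:
        if not (self.vppscale > 0):
            raise ValidationError(f"vppscale must be positive, got {self.vppscale}")
        if self.nonneg_policy not in ("clamp_reassign", "allow_negative"):
            raise ValidationError(f"unknown nonneg_policy {self.nonneg_policy!r}")
        if not (self.cond_limit > 1):
            raise ValidationError("cond_limit must exceed 1")

    def resolved_eps_fz(self, subject: SubjectParams) -> float:
        return 1e-6 * subject.BW if self.eps_fz is None else self.eps_fz


@dataclass
class VppSolution:
    """Per-frame output of the force decomposition.

    All arrays share the frame axis.  ``vpp`` and the VPV columns are NaN on
    non-double-support frames; magnitudes and GRF vectors are zero where a
    foot is unloaded.
    """

    t: np.ndarray
    labels: np.ndarray
    vpp: np.ndarray  # (n, 3)
    vpv_l: np.ndarray  # (n, 3)
    vpv_r: np.ndarray  # (n, 3)
    mag_l: np.ndarray  # (n,)
    mag_r: np.ndarray  # (n,)
    grf_l: np.ndarray  # (n, 3)
    grf_r: np.ndarray  # (n, 3)
    residual: np.ndarray  # (n,)
    flags: np.ndarray  # (n,) uint8
    cop_l: np.ndarray  # (n, 3)
    cop_r: np.ndarray  # (n, 3)

    @property
    def n(self) -> int:
        return self.t.size

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view matching the prediction CSV schema."""
        df = pd.DataFrame({"time": self.t, "support": self.labels})
        for name, arr in (("grf_l", self.grf_l), ("grf_r", self.grf_r)):
            for j, ax in enumerate("xyz"):
                df[f"{name}_{ax}"] = arr[:, j]
        for name, arr in (("cop_l", self.cop_l), ("cop_r", self.cop_r)):
            for j, ax in enumerate("xy"):
                df[f"{name}_{ax}"] = arr[:, j]
        for j, ax in enumerate("xyz"):
            df[f"vpp_{ax}"] = self.vpp[:, j]
        df["residual"] = self.residual
        df["flags"] = [flags_to_str(int(f)) for f in self.flags]
        return df


def compute_vpp(
    com: np.ndarray,
    f_com: np.ndarray,
    params: VppParams,
    subject: SubjectParams,
    vppscale: float | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """VPP position(s) from COM position(s) and resultant COM force(s).

    Accepts single 3-vectors or ``(n, 3)`` arrays.  Returns ``(vpp,
    degenerate)`` where ``degenerate`` marks frames with |F_COM(z)| below
    ``eps_fz``; those fall back to VPP(x, y) = COM(x, y).

    ``vppscale`` may be a scalar or a per-frame array (time-varying scale
    hook); defaults to ``params.vppscale``.
    """
    com = np.atleast_2d(np.asarray(com, dtype=float))
    f_com = np.atleast_2d(np.asarray(f_com, dtype=float))
    if com.shape != f_com.shape or com.shape[1] != 3:
        raise ValidationError("com and f_com must both have shape (n, 3)")
    scale = params.vppscale if vppscale is None else vppscale
    eps = params.resolved_eps_fz(subject)
    fz = f_com[:, 2]
    degenerate = np.abs(fz) < eps
    ratio = np.zeros_like(fz)
    np.divide(com[:, 2], fz, out=ratio, where=~degenerate)
    vpp = np.empty_like(com)
    vpp[:, :2] = com[:, :2] + ratio[:, None] * f_com[:, :2]
    vpp[:, 2] = np.asarray(scale, dtype=float) * subject.BH
    return vpp, degenerate


def compute_vpv(vpp: np.ndarray, cop: np.ndarray) -> np.ndarray:
    """Unit vector(s) from COP to VPP.  Raises on coincident points."""
    vpp = np.asarray(vpp, dtype=float)
    cop = np.asarray(cop, dtype=float)
    d = vpp - cop
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(norm == 0.0):
        raise ValidationError("VPP coincides with a COP; direction undefined")
    return d / norm


def _solve_pairs(
    f_com: np.ndarray,
    vpv_l: np.ndarray,
    vpv_r: np.ndarray,
    params: VppParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised least-squares magnitudes for (n, 3) batches of unit directions.

    For unit columns the normal equations of ``[vpv_l vpv_r]·(a,b)ᵀ = F`` are
    the closed 2×2 system [[1, c], [c, 1]]·(a,b)ᵀ = (vl·F, vr·F) with
    c = vl·vr; its solution is the unique minimum-residual least-squares
    solution whenever the directions are independent.  The condition number
    of the 3×2 matrix is sqrt((1+|c|)/(1-|c|)).

    Returns (a, b, residual, flags).
    """
    f_com = np.atleast_2d(f_com)
    vpv_l = np.atleast_2d(vpv_l)
    vpv_r = np.atleast_2d(vpv_r)
    n = f_com.shape[0]
    flags = np.zeros(n, dtype=np.uint8)

    c = np.einsum("ij,ij->i", vpv_l, vpv_r)
    p = np.einsum("ij,ij->i", vpv_l, f_com)
    q = np.einsum("ij,ij->i", vpv_r, f_com)

    abs_c = np.minimum(np.abs(c), 1.0)
    # cond^2 = (1+|c|)/(1-|c|); compare squared to avoid sqrt of inf
    with np.errstate(divide="ignore"):
        cond_sq = (1.0 + abs_c) / (1.0 - abs_c)
    ill = ~np.isfinite(cond_sq) | (cond_sq > params.cond_limit**2)
    # NaN directions (undefined VPV) are treated as ill-conditioned frames
    ill |= ~(np.isfinite(vpv_l).all(axis=1) & np.isfinite(vpv_r).all(axis=1))
    flags[ill] |= FLAG_ILL_CONDITIONED

    det = 1.0 - c * c
    safe = ~ill
    a = np.zeros(n)
    b = np.zeros(n)
    np.divide(p - c * q, det, out=a, where=safe)
    np.divide(q - c * p, det, out=b, where=safe)

    if params.nonneg_policy == "clamp_reassign":
        neg_l = safe & (a < 0.0)
        neg_r = safe & (b < 0.0)
        both = neg_l & neg_r
        only_l = neg_l & ~both
        only_r = neg_r & ~both
        # zero the negative foot, refit the other as a 1-D projection
        a[only_l] = 0.0
        b[only_l] = np.maximum(q[only_l], 0.0)
        b[only_r] = 0.0
        a[only_r] = np.maximum(p[only_r], 0.0)
        if np.any(both):
            # pick the single-foot fit with the smaller residual
            fb = f_com[both]
            ra = np.linalg.norm(fb - np.maximum(p[both], 0.0)[:, None] * vpv_l[both], axis=1)
            rb = np.linalg.norm(fb - np.maximum(q[both], 0.0)[:, None] * vpv_r[both], axis=1)
            use_a = ra <= rb
            ia = np.flatnonzero(both)
            a[ia] = np.where(use_a, np.maximum(p[both], 0.0), 0.0)
            b[ia] = np.where(use_a, 0.0, np.maximum(q[both], 0.0))
        flags[neg_l | neg_r] |= FLAG_CLAMPED

    # ill-conditioned fallback: split 50/50 along the mean direction
    if np.any(ill):
        m = np.nan_to_num(vpv_l[ill]) + np.nan_to_num(vpv_r[ill])
        mn = np.linalg.norm(m, axis=1, keepdims=True)
        fallback_dir = np.where(mn > 1e-12, m / np.where(mn > 0, mn, 1.0), [[0.0, 0.0, 1.0]])
        mag = 0.5 * np.einsum("ij,ij->i", fallback_dir, f_com[ill])
        if params.nonneg_policy == "clamp_reassign":
            mag = np.maximum(mag, 0.0)
        a[ill] = mag
        b[ill] = mag
        # both feet share the fallback direction; recompose for the residual
        recomposed = 2.0 * mag[:, None] * fallback_dir
        res_ill = np.linalg.norm(recomposed - f_com[ill], axis=1)
    recomposed_ok = a[:, None] * np.where(np.isfinite(vpv_l), vpv_l, 0.0) + b[
        :, None
    ] * np.where(np.isfinite(vpv_r), vpv_r, 0.0)
    residual = np.linalg.norm(recomposed_ok - f_com, axis=1)
    if np.any(ill):
        residual[ill] = res_ill
    return a, b, residual, flags


def solve_double_support(
    f_com: np.ndarray,
    vpv_l: np.ndarray,
    vpv_r: np.ndarray,
    params: VppParams = VppParams(),
) -> tuple[float, float, float]:
    """Scalar-frame least-squares magnitudes (GRF_L, GRF_R, residual).

    Raises :class:`IllConditionedError` when the two directions are parallel
    beyond ``params.cond_limit`` (the batch solver in :func:`predict_grf`
    handles that case with a flagged 50/50 fallback instead).
    """
    a, b, res, flags = _solve_pairs(
        np.asarray(f_com, dtype=float),
        np.asarray(vpv_l, dtype=float),
        np.asarray(vpv_r, dtype=float),
        params,
    )
    if flags[0] & FLAG_ILL_CONDITIONED:
        raise IllConditionedError("virtual pivot vectors are numerically parallel")
    return float(a[0]), float(b[0]), float(res[0])


def predict_grf(
    com_force: Trajectory,
    com: Trajectory,
    contact_l: FootContact,
    contact_r: FootContact,
    labels: np.ndarray,
    params: VppParams = VppParams(),
    subject: SubjectParams | None = None,
    scale_series: np.ndarray | None = None,
) -> VppSolution:
    """Per-frame left/right GRF prediction.

    Dispatch: double-support frames run the VPP decomposition; single-support
    frames assign the whole F_COM to the stance foot at its COP; flight frames
    yield zero forces.  Degenerate or ill-conditioned frames are flagged, not
    fatal.

    ``scale_series`` optionally supplies a per-frame VPPscale (time-varying
    hook); by default ``params.vppscale`` is used throughout.
    """
    if subject is None:
        raise ValidationError("subject parameters are required")
    n = com_force.n
    for name, length in (
        ("com", com.n),
        ("labels", len(labels)),
        ("left contact", contact_l.defined.size),
        ("right contact", contact_r.defined.size),
    ):
        if length != n:
            raise ValidationError(f"{name} length {length} does not match force length {n}")

    F = com_force.v
    labels = np.asarray(labels)
    vpp = np.full((n, 3), np.nan)
    vpv_l = np.full((n, 3), np.nan)
    vpv_r = np.full((n, 3), np.nan)
    mag_l = np.zeros(n)
    mag_r = np.zeros(n)
    grf_l = np.zeros((n, 3))
    grf_r = np.zeros((n, 3))
    residual = np.zeros(n)
    flags = np.zeros(n, dtype=np.uint8)

    sl = labels == SINGLE_L
    sr = labels == SINGLE_R
    grf_l[sl] = F[sl]
    mag_l[sl] = np.linalg.norm(F[sl], axis=1)
    grf_r[sr] = F[sr]
    mag_r[sr] = np.linalg.norm(F[sr], axis=1)

    d = labels == DOUBLE
    if np.any(d):
        scale = (
            np.asarray(scale_series, dtype=float)[d]
            if scale_series is not None
            else params.vppscale
        )
        vpp_d, degen = compute_vpp(com.v[d], F[d], params, subject, vppscale=scale)
        flags_d = np.where(degen, FLAG_DEGENERATE_FZ, 0).astype(np.uint8)

        def _unit(delta: np.ndarray) -> np.ndarray:
            norm = np.linalg.norm(delta, axis=1, keepdims=True)
            out = np.full_like(delta, np.nan)
            np.divide(delta, norm, out=out, where=norm > 0)
            return out

        ul = _unit(vpp_d - contact_l.cop[d])
        ur = _unit(vpp_d - contact_r.cop[d])
        a, b, res, fl = _solve_pairs(F[d], ul, ur, params)
        vpp[d] = vpp_d
        vpv_l[d] = ul
        vpv_r[d] = ur
        mag_l[d] = a
        mag_r[d] = b
        ill = (fl & FLAG_ILL_CONDITIONED).astype(bool)
        # ill-conditioned frames load both feet along the shared mean direction
        dir_l = np.where(np.isfinite(ul), ul, 0.0)
        dir_r = np.where(np.isfinite(ur), ur, 0.0)
        if np.any(ill):
            m = dir_l[ill] + dir_r[ill]
            mn = np.linalg.norm(m, axis=1, keepdims=True)
            shared = np.where(mn > 1e-12, m / np.where(mn > 0, mn, 1.0), [[0.0, 0.0, 1.0]])
            dir_l[ill] = shared
            dir_r[ill] = shared
        grf_l[d] = a[:, None] * dir_l
        grf_r[d] = b[:, None] * dir_r
        residual[d] = res
        flags[d] = flags_d | fl

    return VppSolution(
        t=com_force.t.copy(),
        labels=labels.astype("<U8"),
        vpp=vpp,
        vpv_l=vpv_l,
        vpv_r=vpv_r,
        mag_l=mag_l,
        mag_r=mag_r,
        grf_l=grf_l,
        grf_r=grf_r,
        residual=residual,
        flags=flags,
        cop_l=contact_l.cop.copy(),
        cop_r=contact_r.cop.copy(),
    )


def baseline_even_split(
    com_force: Trajectory,
    labels: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """COM-only baseline: split F_COM 50/50 between the feet, no pivot geometry.

    Single-support frames assign the whole force to the stance foot, flight
    frames zero — identical dispatch to :func:`predict_grf`, but double
    support divides the resultant evenly instead of routing it through a VPP.
    With a laterally quiet COM this baseline produces exactly zero lateral
    per-foot force, unlike the measured (and VPP-predicted) equal-opposite
    lateral forces.
    """
    labels = np.asarray(labels)
    F = com_force.v
    grf_l = np.zeros_like(F)
    grf_r = np.zeros_like(F)
    d = labels == DOUBLE
    grf_l[d] = 0.5 * F[d]
    grf_r[d] = 0.5 * F[d]
    sl = labels == SINGLE_L
    sr = labels == SINGLE_R
    grf_l[sl] = F[sl]
    grf_r[sr] = F[sr]
    return grf_l, grf_r
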