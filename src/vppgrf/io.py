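"""CSV/JSON/YAML input-output and the run configuration.

All files are plain text.  Times are seconds, positions metres, forces
Newtons; body-weight normalisation appears only in evaluation outputs.

Schemas
-------
COM kinematics      : ``time,com_x,com_y,com_z``
Segment kinematics  : ``time,<seg>_x,<seg>_y,<seg>_z,...``
Contact points      : ``time,L_cp01_x,L_cp01_y,L_cp01_z,...,R_cp18_z``
Reference GRFs      : ``time,grf_l_x,...,grf_r_z``
Prediction          : ``time,support,grf_l_x..z,grf_r_x..z,cop_l_x,cop_l_y,
                      cop_r_x,cop_r_y,vpp_x..z,residual,flags``
Sweep report        : ``scale,direction,trial,rmse_bw``
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .contact import ContactParams, ContactPointSet
from .errors import ParseError, ValidationError
from .evaluation import DEFAULT_GRID, DIRECTIONS, SweepResult
from .kinematics import SegmentSet, SubjectParams, Trajectory
from .solver import VppParams, VppSolution

logger = logging.getLogger("vppgrf")

_UNIFORM_DT_TOL = 1e-9


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        # round_trip parsing: shortest-repr floats reload bit-exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if "time" not in df.columns:
        raise ParseError(f"{path}: missing required column 'time'")
    return df


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in required and c != "time"]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)


def _check_time(t: np.ndarray, path) -> None:
    if t.size >= 2:
        dts = np.diff(t)
        bad = np.flatnonzero(np.abs(dts - dts[0]) > _UNIFORM_DT_TOL)
        if dts[0] <= 0 or bad.size:
            row = int(bad[0]) + 1 if bad.size else 1
            raise ParseError(f"{path}: non-uniform time step at row {row + 1}")


def _check_finite(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for c in cols:
        vals = df[c].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ParseError(f"{path}: non-finite value in column {c!r}, row {int(bad[0]) + 2}")


# ---------------------------------------------------------------------------
# COM / segment kinematics


def write_com_csv(traj: Trajectory, path) -> None:
    df = pd.DataFrame({"time": traj.t})
    for j, ax in enumerate("xyz"):
        df[f"com_{ax}"] = traj.v[:, j]
    df.to_csv(path, index=False, float_format="%.17g")


def read_com_csv(path) -> Trajectory:
    df = _read_csv(path)
    cols = [f"com_{ax}" for ax in "xyz"]
    _check_columns(df, cols, path)
    _check_finite(df, ["time", *cols], path)
    t = df["time"].to_numpy(dtype=float)
    _check_time(t, path)
    return Trajectory(t, df[cols].to_numpy(dtype=float))


def write_segments_csv(segments: SegmentSet, path) -> None:
    df = pd.DataFrame({"time": segments.trajectories[0].t})
    for name, tr in zip(segments.names, segments.trajectories):
        for j, ax in enumerate("xyz"):
            df[f"{name}_{ax}"] = tr.v[:, j]
    df.to_csv(path, index=False, float_format="%.17g")


def read_segments_csv(path, mass_fractions: dict) -> SegmentSet:
    """Read segment-COM trajectories; ``mass_fractions`` maps name -> share."""
    df = _read_csv(path)
    t = df["time"].to_numpy(dtype=float)
    _check_time(t, path)
    names, fracs, trajs = [], [], []
    for name, frac in mass_fractions.items():
        cols = [f"{name}_{ax}" for ax in "xyz"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing} for segment {name!r}")
        _check_finite(df, cols, path)
        names.append(name)
        fracs.append(frac)
        trajs.append(Trajectory(t, df[cols].to_numpy(dtype=float)))
    return SegmentSet(tuple(names), np.asarray(fracs, dtype=float), tuple(trajs))


# ---------------------------------------------------------------------------
# Contact points


def _cp_cols(side: str, n_cp: int) -> list:
    return [f"{side}_cp{i + 1:02d}_{ax}" for i in range(n_cp) for ax in "xyz"]


def write_contacts_csv(cps_l: ContactPointSet, cps_r: ContactPointSet, path) -> None:
    data = {"time": cps_l.t}
    for side, cps in (("L", cps_l), ("R", cps_r)):
        flat = cps.p.reshape(cps.n_frames, cps.n_cp * 3)
        for k, col in enumerate(_cp_cols(side, cps.n_cp)):
            data[col] = flat[:, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_contacts_csv(path) -> tuple:
    df = _read_csv(path)
    t = df["time"].to_numpy(dtype=float)
    _check_time(t, path)
    out = []
    for side in ("L", "R"):
        n_cp = sum(1 for c in df.columns if c.startswith(f"{side}_cp") and c.endswith("_x"))
        if n_cp == 0:
            raise ParseError(f"{path}: no contact-point columns for side {side}")
        cols = _cp_cols(side, n_cp)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        _check_finite(df, cols, path)
        p = df[cols].to_numpy(dtype=float).reshape(t.size, n_cp, 3)
        out.append(ContactPointSet(t, p))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# GRFs


def write_grf_csv(t: np.ndarray, grf_l: np.ndarray, grf_r: np.ndarray, path) -> None:
    df = pd.DataFrame({"time": np.asarray(t, dtype=float)})
    for name, arr in (("grf_l", np.asarray(grf_l)), ("grf_r", np.asarray(grf_r))):
        for j, ax in enumerate("xyz"):
            df[f"{name}_{ax}"] = arr[:, j]
    df.to_csv(path, index=False, float_format="%.17g")


def read_grf_csv(path) -> tuple:
    df = _read_csv(path)
    cols = [f"grf_{s}_{ax}" for s in "lr" for ax in "xyz"]
    _check_columns(df, cols, path)
    _check_finite(df, ["time", *cols], path)
    t = df["time"].to_numpy(dtype=float)
    _check_time(t, path)
    g = df[cols].to_numpy(dtype=float)
    return t, g[:, :3], g[:, 3:]


def write_prediction_csv(sol: VppSolution, path) -> None:
    sol.to_dataframe().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Sweep report / summary


def write_sweep_csv(results: Sequence[SweepResult], path) -> None:
    rows = []
    for idx, r in enumerate(results):
        trial = r.trial_id or f"{r.trial_kind or 'trial'}_{idx}"
        for i, s in enumerate(r.scales):
            for j, d in enumerate(DIRECTIONS):
                rows.append({"scale": s, "direction": d, "trial": trial, "rmse_bw": r.rmse[i, j]})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_sweep_summary_json(results: Sequence[SweepResult], optimum: float, path) -> None:
    """Summary JSON: selected optimum plus per-direction medians/IQRs there."""
    results = list(results)
    grid = results[0].scales
    i_opt = int(np.argmin(np.abs(grid - optimum)))
    per_dir = {}
    for j, d in enumerate(DIRECTIONS):
        vals = np.array([r.rmse[i_opt, j] for r in results])
        per_dir[d] = {
            "median_rmse_bw": float(np.median(vals)),
            "iqr_rmse_bw": [float(np.percentile(vals, 25)), float(np.percentile(vals, 75))],
        }
    payload = {
        "optimum_vppscale": float(optimum),
        "n_trials": len(results),
        "per_direction_at_optimum": per_dir,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Whole-trial round trip


def save_trial(trial, prefix) -> None:
    """Write a trial as ``<prefix>_{com,contacts,grf}.csv`` + ``<prefix>_meta.json``.

    The exported kinematics CSVs use the same schemas the readers consume,
    so generated trials are indistinguishable from imported ones.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_com_csv(trial.com, f"{prefix}_com.csv")
    write_contacts_csv(trial.contacts_l, trial.contacts_r, f"{prefix}_contacts.csv")
    write_grf_csv(trial.com.t, trial.truth_grf_l, trial.truth_grf_r, f"{prefix}_grf.csv")
    meta = {
        "kind": trial.kind,
        "sample_rate": trial.sample_rate,
        "seed": trial.seed,
        "true_vppscale": trial.true_vppscale,
        "noise_sigma": trial.noise_sigma,
        "subject": {"M": trial.subject.M, "BH": trial.subject.BH, "g_mag": trial.subject.g_mag},
        "meta": trial.meta,
    }
    Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


def load_trial(prefix, contact_params: ContactParams = ContactParams()):
    """Read a trial saved by :func:`save_trial`; labels are recomputed.

    The returned trial's ``com_clean`` aliases the exported COM (noise, if
    any, was applied before export and the clean signal is not persisted).
    """
    from .contact import classify_support, compute_cop, contact_weights
    from .synthetic import SyntheticTrial

    prefix = Path(prefix)
    com = read_com_csv(f"{prefix}_com.csv")
    cps_l, cps_r = read_contacts_csv(f"{prefix}_contacts.csv")
    t, grf_l, grf_r = read_grf_csv(f"{prefix}_grf.csv")
    if t.size != com.n:
        raise ParseError(f"{prefix}: GRF and kinematics files disagree on length")
    meta = json.loads(Path(f"{prefix}_meta.json").read_text())
    subject = SubjectParams(**meta["subject"])
    fc_l = compute_cop(contact_weights(cps_l, contact_params), cps_l, contact_params)
    fc_r = compute_cop(contact_weights(cps_r, contact_params), cps_r, contact_params)
    labels = classify_support(fc_l, fc_r)
    return SyntheticTrial(
        subject=subject,
        kind=meta["kind"],
        sample_rate=meta["sample_rate"],
        seed=meta["seed"],
        true_vppscale=meta["true_vppscale"],
        noise_sigma=meta["noise_sigma"],
        com=com,
        com_clean=com,
        contacts_l=cps_l,
        contacts_r=cps_r,
        truth_grf_l=grf_l,
        truth_grf_r=grf_r,
        truth_cop_l=fc_l.cop.copy(),
        truth_cop_r=fc_r.cop.copy(),
        labels=labels,
        meta=meta.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Bundle of all pipeline parameters; round-trips through YAML.

    ``force_cutoff_hz`` / ``cop_cutoff_hz`` are the zero-phase Butterworth
    cutoffs applied to measured force and COP signals (20 and 40 Hz by
    default); ``com_cutoff_hz`` optionally smooths kinematic positions before
    differentiation (off by default; 6 Hz is a sensible value for noisy
    input).  Cutoffs are validated against the data's Nyquist frequency at
    filter time.
    """

    subject: SubjectParams = field(default_factory=lambda: SubjectParams(M=75.0, BH=1.75))
    contact: ContactParams = field(default_factory=ContactParams)
    vpp: VppParams = field(default_factory=VppParams)
    grid: tuple = tuple(float(s) for s in DEFAULT_GRID)
    force_cutoff_hz: float | None = 20.0
    cop_cutoff_hz: float | None = 40.0
    com_cutoff_hz: float | None = None
    filter_order: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = tuple(float(s) for s in self.grid)
        if len(self.grid) == 0:
            raise ValidationError("empty sweep grid in config")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValidationError("sweep grid must be strictly increasing")

    def to_yaml(self, path) -> None:
        payload = {
            "subject": asdict(self.subject),
            "contact": asdict(self.contact),
            "vpp": asdict(self.vpp),
            "grid": list(self.grid),
            "filters": {
                "force_cutoff_hz": self.force_cutoff_hz,
                "cop_cutoff_hz": self.cop_cutoff_hz,
                "com_cutoff_hz": self.com_cutoff_hz,
                "order": self.filter_order,
            },
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        filters = raw.get("filters", {})
        return cls(
            subject=SubjectParams(**raw["subject"]),
            contact=ContactParams(**raw.get("contact", {})),
            vpp=VppParams(**raw.get("vpp", {})),
            grid=tuple(raw.get("grid", DEFAULT_GRID)),
            force_cutoff_hz=filters.get("force_cutoff_hz", 20.0),
            cop_cutoff_hz=filters.get("cop_cutoff_hz", 40.0),
            com_cutoff_hz=filters.get("com_cutoff_hz"),
            filter_order=filters.get("order", 2),
            seed=raw.get("seed", 0),
        )
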