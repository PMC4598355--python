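"""Trajectory containers, CSV I/O and kinematic series.

A trajectory is a uniformly sampled planar track: time, position (cm) and
velocity (cm/s).  From it we derive the three kinematic signals the rest of
the package consumes: instantaneous speed ``u`` (norm of the velocity),
signed turning speed ``omega`` (rate of change of the velocity orientation,
anticlockwise/left positive) and heading ``phi`` (velocity angle).

The CSV dialect is a header row ``t,x,y,vx,vy`` preceded by ``#`` comment
lines stating units; a ``frame`` column may replace ``t`` when a sampling
rate is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "KinematicSeries",
    "wrap_angle",
    "read_trajectory",
    "write_trajectory",
    "compute_speed",
    "compute_turning_speed",
    "reconstruct_heading",
    "compute_kinematics",
]

_DT_RTOL = 1e-9


def wrap_angle(a):
    """Wrap angle(s) into the half-open interval [-pi, pi).

    The shift-mod-shift form maps +pi to -pi, which keeps headings unique.
    """
    return (np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi


@dataclass
class Trajectory:
    """Uniformly sampled planar position/velocity series.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing with uniform step.
    x, y : ndarray
        Position in cm (origin at the arena/tank centre).
    vx, vy : ndarray
        Velocity in cm/s.
    subject_id : str
        Label of the tracked subject (e.g. ``"F7"``).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    subject_id: str = "subject"

    def __post_init__(self):
        for name in ("t", "x", "y", "vx", "vy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if n < 2:
            raise ValueError("trajectory needs at least 2 samples")
        for name in ("x", "y", "vx", "vy"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")
            if not np.all(np.isfinite(getattr(self, name))):
                bad = np.flatnonzero(~np.isfinite(getattr(self, name)))
                raise ValueError(f"non-finite values in {name!r} at rows {bad.tolist()}")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite time values")
        diffs = np.diff(self.t)
        dt = float(np.median(diffs))
        if dt <= 0:
            raise ValueError("time must be strictly increasing")
        bad = np.flatnonzero(np.abs(diffs - dt) > _DT_RTOL * dt)
        if bad.size:
            raise ValueError(
                "non-uniform sampling: steps at indices "
                f"{bad.tolist()} deviate from dt={dt:g}"
            )

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)

    def slice(self, start: int, stop: int, subject_id: str | None = None) -> "Trajectory":
        """Contiguous sub-trajectory over sample indices [start, stop)."""
        return Trajectory(
            self.t[start:stop],
            self.x[start:stop],
            self.y[start:stop],
            self.vx[start:stop],
            self.vy[start:stop],
            subject_id=subject_id or self.subject_id,
        )


@dataclass
class KinematicSeries:
    """Speed, turning speed and heading derived from one trajectory.

    ``omega_mask`` flags samples where the turning speed is not measurable
    (zero-speed samples and the forward-difference padding at the end);
    those entries are set to 0 rad/s.
    """

    u: np.ndarray
    omega: np.ndarray
    phi: np.ndarray
    dt: float
    omega_mask: np.ndarray = field(default=None)


def read_trajectory(path, fs: float | None = None, subject_id: str | None = None) -> Trajectory:
    """Read a trajectory CSV.

    Accepts columns ``t,x,y[,vx,vy]`` or ``frame,x,y[,vx,vy]``; with a
    ``frame`` column the sampling rate ``fs`` (Hz) is required to convert
    to seconds.  Missing velocity columns are reconstructed by backwards
    differences of position (first sample copied from the second).

    A leading ``# subject_id: <label>`` comment line (as emitted by
    :func:`write_trajectory`) sets the subject label unless one is passed
    explicitly.
    """
    if subject_id is None:
        try:
            with open(path) as fh:
                for line in fh:
                    if not line.startswith("#"):
                        break
                    if "subject_id:" in line:
                        subject_id = line.split("subject_id:", 1)[1].strip()
        except (OSError, UnicodeDecodeError):
            pass
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    cols = {c.strip(): c for c in df.columns}
    if "t" in cols:
        t = df[cols["t"]].to_numpy(dtype=float)
    elif "frame" in cols:
        if fs is None:
            raise ValueError("'frame' column present but no sampling rate given")
        t = df[cols["frame"]].to_numpy(dtype=float) / fs
    else:
        raise ValueError("need a 't' or 'frame' column")
    for req in ("x", "y"):
        if req not in cols:
            raise ValueError(f"missing column {req!r}")
    nan_rows = np.flatnonzero(df[[cols[c] for c in ("x", "y") if c in cols]].isna().any(axis=1).to_numpy())
    if nan_rows.size:
        raise ValueError(f"NaN values at rows {nan_rows.tolist()}")
    x = df[cols["x"]].to_numpy(dtype=float)
    y = df[cols["y"]].to_numpy(dtype=float)
    if "vx" in cols and "vy" in cols:
        vx = df[cols["vx"]].to_numpy(dtype=float)
        vy = df[cols["vy"]].to_numpy(dtype=float)
        bad = np.flatnonzero(~(np.isfinite(vx) & np.isfinite(vy)))
        if bad.size:
            raise ValueError(f"NaN values at rows {bad.tolist()}")
    else:
        dt = float(np.median(np.diff(t)))
        vx = np.empty_like(x)
        vy = np.empty_like(y)
        vx[1:] = np.diff(x) / dt
        vy[1:] = np.diff(y) / dt
        vx[0], vy[0] = vx[1], vy[1]
    return Trajectory(t, x, y, vx, vy, subject_id=subject_id or "subject")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory in the package CSV dialect (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("# finwalk trajectory: t [s], x y [cm], vx vy [cm/s]\n")
        fh.write(f"# subject_id: {traj.subject_id}\n")
        fh.write("t,x,y,vx,vy\n")
        for row in zip(traj.t, traj.x, traj.y, traj.vx, traj.vy):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def compute_speed(traj: Trajectory) -> np.ndarray:
    """Instantaneous speed u = ||v|| in cm/s."""
    return np.hypot(traj.vx, traj.vy)


def compute_turning_speed(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Signed turning speed (rad/s), anticlockwise (left) positive.

    omega[k] is the signed angle from v[k] to v[k+1] divided by dt, so
    |omega| <= pi/dt, the maximum turn resolvable between two samples.

    Returns ``(omega, mask)``: ``mask`` is True where the value is not a
    measurement — zero-speed samples and the padded final sample, where
    omega is set to 0.

    Antiparallel velocity pairs (angle exactly pi, cross product 0) have no
    intrinsic sign; the sign of the previous non-zero turn is reused, and
    defaults to + at the start of the series.
    """
    dt = traj.dt
    vx, vy = traj.vx, traj.vy
    cross = vx[:-1] * vy[1:] - vy[:-1] * vx[1:]
    dot = vx[:-1] * vx[1:] + vy[:-1] * vy[1:]
    ang = np.arctan2(cross, dot)
    speed = np.hypot(vx, vy)
    zero = (speed[:-1] == 0.0) | (speed[1:] == 0.0)
    ang[zero] = 0.0
    # antiparallel tie-break: deterministic sign carried from the last
    # non-zero turn, + if there is none
    anti = np.flatnonzero((cross == 0.0) & (dot < 0.0) & ~zero)
    for i in anti:
        sign = 1.0
        for j in range(i - 1, -1, -1):
            if ang[j] != 0.0:
                sign = np.sign(ang[j])
                break
        ang[i] = sign * np.pi
    omega = np.append(ang / dt, 0.0)
    mask = np.append(zero, True)
    return omega, mask


def reconstruct_heading(traj: Trajectory) -> np.ndarray:
    """Heading phi (rad, in [-pi, pi)) from the velocity vectors.

    At zero-speed samples the heading is carried forward from the last
    moving sample; a stationary run at the start takes the heading of the
    first moving sample.  A trajectory with no moving sample has no
    defined heading and raises.
    """
    speed = np.hypot(traj.vx, traj.vy)
    moving = speed > 0.0
    if not moving.any():
        raise ValueError("heading undefined: velocity is zero everywhere")
    phi = wrap_angle(np.arctan2(traj.vy, traj.vx))
    idx = np.where(moving, np.arange(len(phi)), -1)
    idx = np.maximum.accumulate(idx)
    idx[idx < 0] = int(np.argmax(moving))
    return phi[idx]


def compute_kinematics(traj: Trajectory) -> KinematicSeries:
    """Bundle speed, turning speed and heading for one trajectory."""
    u = compute_speed(traj)
    omega, mask = compute_turning_speed(traj)
    phi = reconstruct_heading(traj)
    return KinematicSeries(u=u, omega=omega, phi=phi, dt=traj.dt, omega_mask=mask)
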