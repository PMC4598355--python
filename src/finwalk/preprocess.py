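"""Swimming-bout extraction.

Raw tracks mix active swimming with freezing and near-wall thrashing.  The
segmentation keeps only sustained swimming: the speed is smoothed with a
short moving average, thresholded at ``u_min`` body lengths per second,
brief sub-threshold dips (shorter than ``tau_s``) are bridged, and the
surviving runs are cut into consecutive equal-length windows of ``tau_l``
seconds.  Windows carry the original (unsmoothed) samples; the smoothed
speed is used only for thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import Trajectory, compute_speed

__all__ = ["SegmentationConfig", "SwimSegment", "smooth_speed", "segment_swimming"]


@dataclass
class SegmentationConfig:
    """Segmentation thresholds.

    u_min : speed threshold in body lengths per second (default 1 BL/s).
    body_length : cm per body length (default 3 cm for adult zebrafish).
    tau_s : longest sub-threshold gap (s) still counted as swimming.
    tau_l : length (s) of the equal-duration windows returned.
    smooth_window : moving-average width in samples (odd).
    """

    u_min: float = 1.0
    body_length: float = 3.0
    tau_s: float = 2.0
    tau_l: float = 60.0
    smooth_window: int = 3

    def __post_init__(self):
        if self.u_min <= 0:
            raise ValueError("u_min must be positive")
        if self.tau_s < 0 or self.tau_l <= 0:
            raise ValueError("tau_s must be >= 0 and tau_l > 0")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")


@dataclass
class SwimSegment:
    """One equal-length window of swimming data."""

    trajectory: Trajectory
    source_id: str
    start_index: int
    label: int


def smooth_speed(u: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; edges use shrunken windows.

    Used only to decide which samples count as swimming — downstream
    analysis always runs on the unsmoothed data.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    u = np.asarray(u, dtype=float)
    if window > len(u):
        raise ValueError("window longer than series")
    return (
        pd.Series(u).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def _runs(mask: np.ndarray):
    """Contiguous True runs of a boolean mask as (start, stop) index pairs."""
    padded = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def segment_swimming(traj: Trajectory, cfg: SegmentationConfig) -> list[SwimSegment]:
    """Extract equal-length swimming windows from one trajectory.

    Steps: (a) threshold the smoothed speed at ``u_min`` (strict ">", in
    BL/s); (b) join above-threshold runs separated by gaps strictly shorter
    than ``tau_s`` (a gap of exactly ``tau_s`` splits); (c) cut each merged
    run into consecutive windows of round(tau_l/dt) samples, anchored at
    the run start, discarding the trailing remainder.
    """
    dt = traj.dt
    u_bl = compute_speed(traj) / cfg.body_length
    smoothed = smooth_speed(u_bl, cfg.smooth_window)
    above = smoothed > cfg.u_min
    runs = _runs(above)
    if not runs:
        return []
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        gap = (start - merged[-1][1]) * dt
        if gap < cfg.tau_s:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    n_seg = int(round(cfg.tau_l / dt))
    segments: list[SwimSegment] = []
    label = 1
    for start, stop in merged:
        for j in range((stop - start) // n_seg):
            lo = start + j * n_seg
            segments.append(
                SwimSegment(
                    trajectory=traj.slice(lo, lo + n_seg),
                    source_id=traj.subject_id,
                    start_index=int(lo),
                    label=label,
                )
            )
            label += 1
    return segments
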