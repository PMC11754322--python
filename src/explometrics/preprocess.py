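"""Quality control, exclusion screens and resampling of raw trajectories.

The QC screens target artifacts of fixed-speed game logging: because
movement speed is constant, variability in step length is a proxy for
variability in sampling rate, and isolated oversized steps indicate
logging lags.  Screens only *flag* subjects; dropping them is left to
the caller so the effect of each rule stays visible.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from ._kernels import rediscretize_core
from .trajio import DegenerateTrajectoryError, Trajectory

__all__ = [
    "QCParams",
    "QCReport",
    "infer_sampling_rate",
    "step_lengths",
    "turning_angles",
    "signed_turning_angles",
    "qc_screen",
    "cohort_screen",
    "trim_initial_idle",
    "resample_temporal",
    "rediscretize_spatial",
    "rdp_simplify",
]


@dataclass
class QCParams:
    """Exclusion-rule thresholds.

    ``cov_outlier_iqr_mult``: a subject's step-length coefficient of
    variation is an outlier above Q3 + mult * IQR of the cohort CoVs.
    ``lag_step_mult``: a "large lag" is a step longer than mult times
    the subject's median nonzero step.  ``lag_fraction_cutoff``: maximal
    tolerated share of lag steps (0.001 = 0.1%).  Subjects moving for
    less than ``min_movement_seconds`` are flagged as low-movement.
    """

    cov_outlier_iqr_mult: float = 3.0
    lag_step_mult: float = 3.0
    lag_fraction_cutoff: float = 0.001
    min_movement_seconds: float = 30.0
    min_sampling_hz: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "cov_outlier_iqr_mult",
            "lag_step_mult",
            "lag_fraction_cutoff",
            "min_movement_seconds",
            "min_sampling_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.lag_fraction_cutoff < 1):
            raise ValueError("lag_fraction_cutoff must be in (0, 1)")


@dataclass
class QCReport:
    subject_id: str
    sampling_rate_hz: float
    cov_step_length: float
    lag_fraction: float
    movement_seconds: float
    excluded: bool = False
    reasons: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.lag_fraction <= 1.0 or np.isnan(self.lag_fraction)):
            raise ValueError("lag_fraction must be in [0, 1]")
        if bool(self.reasons) != bool(self.excluded):
            raise ValueError("reasons must be non-empty iff excluded")


def infer_sampling_rate(n_points: int, total_time: float) -> float:
    """Sampling rate recovered from the sample count and total play time."""
    if n_points < 2:
        raise DegenerateTrajectoryError("need at least 2 points")
    if total_time <= 0:
        raise ValueError(f"total_time must be positive, got {total_time}")
    return n_points / total_time


def step_lengths(traj: Trajectory) -> np.ndarray:
    """Euclidean distances between consecutive samples (length n-1)."""
    return np.linalg.norm(np.diff(traj.points, axis=0), axis=1)


def _headings(points: np.ndarray, skip_zero_steps: bool, pause_epsilon: float):
    disp = np.diff(points, axis=0)
    lens = np.linalg.norm(disp, axis=1)
    if skip_zero_steps:
        disp = disp[lens > pause_epsilon]
    return disp


def turning_angles(
    traj: Trajectory,
    skip_zero_steps: bool = True,
    pause_epsilon: float = 1e-9,
) -> np.ndarray:
    """Absolute turning angles in degrees, in [0, 180].

    0 means no change in heading direction and 180 a complete reversal.
    With ``skip_zero_steps``, zero-length displacements (pauses) are
    removed before angles are computed, so angles compare successive
    *movement* directions.  If no displacement remains, the result is
    empty.
    """
    if len(traj) < 3:
        raise DegenerateTrajectoryError("turning angles need >= 3 points")
    disp = _headings(traj.points, skip_zero_steps, pause_epsilon)
    if len(disp) < 2:
        return np.empty(0)
    return np.degrees(np.abs(_signed_angles(disp)))


def signed_turning_angles(points: np.ndarray, pause_epsilon: float = 1e-9) -> np.ndarray:
    """Signed turning angles in radians (positive = left turn), pauses skipped."""
    disp = _headings(points, True, pause_epsilon)
    if len(disp) < 2:
        return np.empty(0)
    return _signed_angles(disp)


def _signed_angles(disp: np.ndarray) -> np.ndarray:
    v1, v2 = disp[:-1], disp[1:]
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = np.einsum("ij,ij->i", v1, v2)
    return np.arctan2(cross, dot)


def _resolve_rate(traj: Trajectory, total_time: Optional[float]) -> float:
    if traj.sample_rate_hz is not None:
        return traj.sample_rate_hz
    if total_time is not None:
        return infer_sampling_rate(len(traj), total_time)
    rate = traj.effective_rate()
    if rate is None:
        raise ValueError(
            f"{traj.subject_id}: unknown sampling rate; set sample_rate_hz, "
            "provide timestamps, or pass total_time"
        )
    return rate


def qc_screen(
    traj: Trajectory,
    total_time: Optional[float] = None,
    qc: Optional[QCParams] = None,
    pause_epsilon: float = 1e-9,
) -> QCReport:
    """Per-subject QC quantities and the subject-level exclusion rules.

    Computes the coefficient of variation (sd/mean) of nonzero step
    lengths, the fraction of lag steps (steps longer than
    ``lag_step_mult`` times the median nonzero step) and the total
    movement time (nonzero steps / sampling rate).  Cohort-level CoV
    outlier flagging lives in :func:`cohort_screen`; here only the raw
    CoV is reported.
    """
    qc = qc or QCParams()
    rate = _resolve_rate(traj, total_time)
    steps = step_lengths(traj)
    nonzero = steps[steps > pause_epsilon]
    if len(nonzero) == 0:
        return QCReport(
            subject_id=traj.subject_id,
            sampling_rate_hz=rate,
            cov_step_length=float("nan"),
            lag_fraction=0.0,
            movement_seconds=0.0,
            excluded=True,
            reasons=["no_movement"],
        )
    mean = float(nonzero.mean())
    cov = float(nonzero.std(ddof=1) / mean) if len(nonzero) > 1 else 0.0
    median = float(np.median(nonzero))
    lag_fraction = float(np.mean(steps > qc.lag_step_mult * median))
    movement_seconds = len(nonzero) / rate
    reasons = []
    if movement_seconds < qc.min_movement_seconds:
        reasons.append("low_movement")
    if lag_fraction > qc.lag_fraction_cutoff:
        reasons.append("high_lag")
    return QCReport(
        subject_id=traj.subject_id,
        sampling_rate_hz=rate,
        cov_step_length=cov,
        lag_fraction=lag_fraction,
        movement_seconds=movement_seconds,
        excluded=bool(reasons),
        reasons=reasons,
    )


def cohort_screen(
    reports: Sequence[QCReport], qc: Optional[QCParams] = None
) -> List[QCReport]:
    """Flag cohort-level CoV outliers (CoV > Q3 + mult * IQR of cohort CoVs).

    With fewer than 4 reports the IQR is not meaningful; a warning is
    emitted and the reports pass through unflagged.
    """
    qc = qc or QCParams()
    reports = list(reports)
    if len(reports) < 4:
        warnings.warn("cohort_screen: fewer than 4 subjects, skipping CoV screen")
        return [replace(r, reasons=list(r.reasons)) for r in reports]
    covs = np.array([r.cov_step_length for r in reports])
    valid = covs[~np.isnan(covs)]
    q1, q3 = np.percentile(valid, [25, 75])
    cutoff = q3 + qc.cov_outlier_iqr_mult * (q3 - q1)
    out = []
    for r in reports:
        r = replace(r, reasons=list(r.reasons))
        if not np.isnan(r.cov_step_length) and r.cov_step_length > cutoff:
            r.reasons.append("cov_outlier")
            r.excluded = True
        out.append(r)
    return out


def trim_initial_idle(traj: Trajectory, pause_epsilon: float = 1e-9) -> Trajectory:
    """Drop leading idle samples; the last idle position is retained so
    movement starts at the first step of the result."""
    steps = step_lengths(traj)
    moving = np.nonzero(steps > pause_epsilon)[0]
    if len(moving) == 0:
        raise DegenerateTrajectoryError(f"{traj.subject_id}: no movement at all")
    start = int(moving[0])
    times = traj.times[start:] if traj.times is not None else None
    return traj.with_points(traj.points[start:], times=times)


def resample_temporal(traj: Trajectory, target_hz: float) -> Trajectory:
    """Linearly interpolate positions on a uniform 1/target_hz grid.

    Timestamps are used when present; otherwise synthetic timestamps
    ``i / sample_rate_hz`` are assumed (for loggers without clocks).
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if traj.times is not None:
        times = traj.times
    elif traj.sample_rate_hz is not None:
        times = np.arange(len(traj)) / traj.sample_rate_hz
    else:
        raise ValueError(
            f"{traj.subject_id}: unknown timing; set sample_rate_hz or times"
        )
    dt = 1.0 / target_hz
    n_out = int(np.floor((times[-1] - times[0]) / dt + 1e-9)) + 1
    new_times = times[0] + np.arange(n_out) * dt
    x = np.interp(new_times, times, traj.x)
    y = np.interp(new_times, times, traj.y)
    return traj.with_points(
        np.column_stack([x, y]), times=new_times, sample_rate_hz=target_hz
    )


def rediscretize_spatial(traj: Trajectory, step: float) -> Trajectory:
    """Resample the polyline to exactly constant step length.

    Walks the original polyline and emits a point every time the
    distance from the previously emitted point reaches ``step`` (circle
    intersection with the path, so emitted points lie on the original
    polyline and all emitted steps equal ``step`` to 1e-9).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    total = float(step_lengths(traj).sum())
    if total < step:
        raise DegenerateTrajectoryError(
            f"{traj.subject_id}: path length {total:.3g} shorter than step {step}"
        )
    pts = rediscretize_core(np.ascontiguousarray(traj.points, dtype=float), float(step))
    return traj.with_points(pts, times=None, sample_rate_hz=traj.sample_rate_hz)


def _rdp_keep(points: np.ndarray, epsilon: float, keep: np.ndarray, lo: int, hi: int):
    # perpendicular distance of interior points to the line through the chord
    if hi <= lo + 1:
        return
    a, b = points[lo], points[hi]
    chord = b - a
    norm = np.hypot(*chord)
    interior = points[lo + 1 : hi]
    if norm == 0.0:
        dist = np.linalg.norm(interior - a, axis=1)
    else:
        dist = np.abs(
            (interior[:, 0] - a[0]) * chord[1] - (interior[:, 1] - a[1]) * chord[0]
        ) / norm
    imax = int(np.argmax(dist))  # first maximal point on ties
    if dist[imax] > epsilon:
        mid = lo + 1 + imax
        keep[mid] = True
        _rdp_keep(points, epsilon, keep, lo, mid)
        _rdp_keep(points, epsilon, keep, mid, hi)


def rdp_simplify(traj: Trajectory, epsilon: float) -> Trajectory:
    """Ramer-Douglas-Peucker polyline simplification.

    Recursively keeps the vertex of maximum perpendicular distance from
    the current chord whenever that distance exceeds ``epsilon``; the
    endpoints are always retained.  The result is the flight-scale
    trajectory: each retained segment is one flight.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    pts = traj.points
    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, len(pts) + 100))
    try:
        _rdp_keep(pts, epsilon, keep, 0, len(pts) - 1)
    finally:
        sys.setrecursionlimit(old_limit)
    return traj.with_points(pts[keep], times=None, sample_rate_hz=traj.sample_rate_hz)
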