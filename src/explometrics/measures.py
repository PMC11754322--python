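"""The exploration measures.

Fourteen measures are computed per subject from a preprocessed (trimmed,
temporally resampled) trajectory: extent-of-exploration measures (path
length, pausing, area covered, roaming entropy, minimum convex polygon,
landmark visits), spatial-shape measures (fractal dimension, sinuosity),
and efficiency measures (revisiting, landmark revisits, step- and
flight-scale turnarounds, area and landmark efficiency).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from ._kernels import greedy_centers_core
from .preprocess import (
    rdp_simplify,
    rediscretize_spatial,
    signed_turning_angles,
    step_lengths,
    turning_angles,
)
from .trajio import (
    DegenerateTrajectoryError,
    Environment,
    MeasureParams,
    MeasureRow,
    Trajectory,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BinSequence",
    "VisitLog",
    "bin_sequence",
    "path_length",
    "pausing",
    "area_covered",
    "roaming_entropy",
    "min_convex_polygon",
    "fractal_dimension",
    "sinuosity",
    "landmark_metrics",
    "revisiting",
    "turnarounds",
    "flight_turnarounds",
    "area_efficiency",
    "compute_all",
]


@dataclass
class BinSequence:
    """Grid-cell occupancy of a trajectory.

    ``bins`` holds one (i, j) cell index per sample; ``entries`` is the
    run-length-compressed form of ``bins``: one record per transition
    into a cell different from the previous sample's cell, with the
    first sample counting as an entry.
    """

    bins: np.ndarray  # (n, 2) int
    entries: np.ndarray  # (m, 2) int
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if len(self.bins) == 0:
            raise ValueError("empty bin sequence")


@dataclass
class VisitLog:
    """Ordered entry events into circular targets (landmarks or places)."""

    events: List[Tuple[str, int]]  # (target_id, sample_index), sorted by index

    @property
    def total_entries(self) -> int:
        return len(self.events)

    @property
    def distinct_targets(self) -> int:
        return len({t for t, _ in self.events})


def bin_sequence(traj: Trajectory, env: Environment) -> BinSequence:
    """Assign each sample to its half-open grid cell and compress runs.

    Points outside the bounds are clamped to the border cell and the
    clamp count is reported (and logged).
    """
    xmin, ymin, xmax, ymax = env.bounds
    s = env.bin_size
    ix = np.floor((traj.x - xmin) / s).astype(int)
    iy = np.floor((traj.y - ymin) / s).astype(int)
    out_of_bounds = (
        (traj.x < xmin) | (traj.x > xmax) | (traj.y < ymin) | (traj.y > ymax)
    )
    n_clamped = int(out_of_bounds.sum())
    if n_clamped:
        logger.warning(
            "%s: %d sample(s) outside %s bounds were clamped",
            traj.subject_id,
            n_clamped,
            env.name,
        )
    ix = np.clip(ix, 0, env.n_cols - 1)
    iy = np.clip(iy, 0, env.n_rows - 1)
    bins = np.column_stack([ix, iy])
    changed = np.any(np.diff(bins, axis=0) != 0, axis=1)
    entry_idx = np.concatenate([[0], np.nonzero(changed)[0] + 1])
    return BinSequence(bins=bins, entries=bins[entry_idx], n_clamped=n_clamped)


def path_length(traj: Trajectory) -> float:
    """Total length of the trajectory (sum of step lengths), in vm."""
    return float(step_lengths(traj).sum())


def pausing(traj: Trajectory, params: Optional[MeasureParams] = None) -> float:
    """Time spent without movement, in seconds.

    A step counts as a pause when its length is at most
    ``pause_epsilon``; the pause count is divided by the sampling rate,
    so the measure assumes a uniformly sampled (resampled) trajectory.
    """
    params = params or MeasureParams()
    rate = traj.effective_rate()
    if rate is None:
        raise ValueError(f"{traj.subject_id}: pausing needs a known sampling rate")
    steps = step_lengths(traj)
    return float(np.sum(steps <= params.pause_epsilon) / rate)


def area_covered(bins: BinSequence) -> int:
    """Number of distinct grid cells visited."""
    return len(np.unique(bins.bins, axis=0))


def roaming_entropy(bins: BinSequence, k_norm: int) -> float:
    """Normalized Shannon entropy of per-sample bin occupancy.

    ``RE = -sum_i p_i ln p_i / ln(k_norm)`` with ``p_i`` the share of
    samples spent in cell i.  0 when a single cell is occupied, 1 for
    uniform occupancy of exactly ``k_norm`` cells.
    """
    if k_norm < 2:
        raise ValueError("k_norm must be >= 2 for roaming entropy")
    _, counts = np.unique(bins.bins, axis=0, return_counts=True)
    p = counts / counts.sum()
    ent = float(-(p * np.log(p)).sum())
    return ent / math.log(k_norm) + 0.0  # normalize -0.0


def min_convex_polygon(traj: Trajectory) -> float:
    """Area of the convex hull of all sample points, in vm^2 (0 if collinear)."""
    pts = np.unique(traj.points, axis=0)
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0  # all points collinear
    return float(hull.volume)  # in 2-D, .volume is the area


def fractal_dimension(
    traj: Trajectory, params: Optional[MeasureParams] = None
) -> float:
    """Divider-method fractal dimension of the path.

    The path length ``L(delta)`` is measured with the constant-step
    rediscretizer at ``fd_n_steps`` divider sizes, log-spaced from
    ``fd_min_factor`` to ``fd_max_factor`` times the median nonzero
    step; the dimension is ``1 - slope`` of the least-squares fit of
    ``ln L`` on ``ln delta``.  Straight paths give 1; plane-filling
    paths approach 2.
    """
    params = params or MeasureParams()
    steps = step_lengths(traj)
    nonzero = steps[steps > params.pause_epsilon]
    if len(nonzero) == 0:
        raise DegenerateTrajectoryError(f"{traj.subject_id}: no movement")
    median = float(np.median(nonzero))
    total = float(steps.sum())
    deltas = np.geomspace(
        params.fd_min_factor * median, params.fd_max_factor * median, params.fd_n_steps
    )
    log_d, log_l = [], []
    for d in deltas:
        if total < 2 * d:
            continue  # path too short to be measured at this divider size
        try:
            rd = rediscretize_spatial(traj, float(d))
        except DegenerateTrajectoryError:
            # confined path never reaches distance d from its start
            continue
        log_d.append(math.log(d))
        log_l.append(math.log((len(rd) - 1) * d))
    if len(log_d) < 3:
        raise DegenerateTrajectoryError(
            f"{traj.subject_id}: fewer than 3 valid divider sizes"
        )
    slope = np.polyfit(log_d, log_l, 1)[0]
    return float(1.0 - slope)


def sinuosity(traj: Trajectory, params: Optional[MeasureParams] = None) -> float:
    """Sinuosity index ``1.18 * sigma / sqrt(q)`` for constant-step paths.

    ``sigma`` is the standard deviation (radians) of the signed turning
    angles and ``q`` the (constant) step length; the caller provides a
    trajectory already rediscretized to constant step (see
    :func:`compute_all`).  Units: rad * vm^(-1/2).
    """
    params = params or MeasureParams()
    if len(traj) < 3:
        raise DegenerateTrajectoryError(f"{traj.subject_id}: need >= 3 points")
    steps = step_lengths(traj)
    nonzero = steps[steps > params.pause_epsilon]
    if len(nonzero) == 0:
        raise DegenerateTrajectoryError(f"{traj.subject_id}: no movement")
    q = float(np.median(nonzero))
    angles = signed_turning_angles(traj.points, params.pause_epsilon)
    if len(angles) == 0:
        return 0.0
    sigma = float(np.std(angles))
    return 1.18 * sigma / math.sqrt(q)


def _entry_events(inside: np.ndarray) -> np.ndarray:
    """Sample indices where ``inside`` flips from False to True (index 0 counts)."""
    trans = np.nonzero(inside[1:] & ~inside[:-1])[0] + 1
    if inside[0]:
        trans = np.concatenate([[0], trans])
    return trans


def landmark_metrics(
    traj: Trajectory,
    env: Environment,
    params: Optional[MeasureParams] = None,
) -> Tuple[int, int, float, VisitLog]:
    """Landmark visits, revisits, efficiency, and the raw visit log.

    A landmark is entered at each transition from outside to inside its
    disc of radius ``landmark_radius`` (the first sample inside counts;
    re-entry requires fully leaving the disc first).  Visits is the
    number of distinct landmarks entered, revisits the number of
    additional entries, and efficiency the ratio visits / total entries
    (NaN, logged, when no landmark is ever entered).
    """
    params = params or MeasureParams()
    if not env.landmarks:
        raise ValueError(f"{env.name}: landmark metrics need >= 1 landmark")
    events: List[Tuple[str, int]] = []
    r2 = params.landmark_radius**2
    for lm in env.landmarks:
        d2 = (traj.x - lm.x) ** 2 + (traj.y - lm.y) ** 2
        for idx in _entry_events(d2 <= r2):
            events.append((lm.id, int(idx)))
    events.sort(key=lambda e: (e[1], e[0]))
    log = VisitLog(events=events)
    visits = log.distinct_targets
    total = log.total_entries
    revisits = total - visits
    if total == 0:
        logger.info("%s: no landmark entered; landmark_efficiency undefined",
                    traj.subject_id)
        return 0, 0, float("nan"), log
    return visits, revisits, visits / total, log


def revisiting(traj: Trajectory, params: Optional[MeasureParams] = None) -> float:
    """Mean number of returns to already visited places.

    Place centers are chosen greedily along the trajectory: the first
    sample is a center, and every later sample farther than
    ``revisit_radius`` from all existing centers opens a new one.
    Entries into each center's disc are counted like landmark entries;
    the measure is the mean over centers of (entries - 1).
    """
    params = params or MeasureParams()
    r = params.revisit_radius
    centers = greedy_centers_core(
        np.ascontiguousarray(traj.points, dtype=float), float(r)
    )
    d2 = (
        (traj.x[None, :] - centers[:, 0:1]) ** 2
        + (traj.y[None, :] - centers[:, 1:2]) ** 2
    )
    inside = d2 <= r * r
    trans = inside[:, 1:] & ~inside[:, :-1]
    entries = trans.sum(axis=1) + inside[:, 0]
    return float(np.mean(entries - 1))


def turnarounds(traj: Trajectory, params: Optional[MeasureParams] = None) -> int:
    """Step-scale turnarounds: turning angles at (or within ``angle_tol``
    degrees of) the full-reversal cutoff, pauses skipped."""
    params = params or MeasureParams()
    angles = turning_angles(traj, skip_zero_steps=True,
                            pause_epsilon=params.pause_epsilon)
    return int(np.sum(angles >= params.step_turn_cutoff - params.angle_tol))


def flight_turnarounds(traj: Trajectory, params: Optional[MeasureParams] = None) -> int:
    """Flight-scale turnarounds.

    The trajectory is simplified to flights (RDP at ``rdp_epsilon``);
    turning angles of at least ``flight_turn_cutoff`` degrees on the
    simplified polyline are counted.  The sub-180 cutoff absorbs the
    small heading jitter that keeps real reversals from hitting 180
    exactly.
    """
    params = params or MeasureParams()
    simplified = rdp_simplify(traj, params.rdp_epsilon)
    return _flight_turnarounds_simplified(simplified, params)


def _flight_turnarounds_simplified(
    simplified: Trajectory, params: MeasureParams
) -> int:
    if len(simplified) < 3:
        return 0
    angles = turning_angles(simplified, skip_zero_steps=True,
                            pause_epsilon=params.pause_epsilon)
    return int(np.sum(angles >= params.flight_turn_cutoff))


def area_efficiency(bins: BinSequence) -> float:
    """Distinct cells / total cell entries; 1 when no cell is re-entered."""
    distinct = len(np.unique(bins.entries, axis=0))
    return distinct / len(bins.entries)


def compute_all(
    traj: Trajectory,
    env: Environment,
    params: Optional[MeasureParams] = None,
) -> MeasureRow:
    """All measures for one subject, sharing intermediates.

    One bin sequence, one constant-step rediscretization (at
    ``rediscretize_step``, defaulting to the subject's median nonzero
    step when unset) and one RDP pass are computed and reused.  The
    input is expected to be preprocessed (trimmed, resampled).
    """
    params = params or MeasureParams()

    def _run(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise type(exc)(f"{traj.subject_id}: measure {name!r} failed: {exc}") from exc

    bins = _run("bin_sequence", bin_sequence, traj, env)
    steps = step_lengths(traj)
    nonzero = steps[steps > params.pause_epsilon]
    q = params.rediscretize_step
    if q is None:
        q = float(np.median(nonzero)) if len(nonzero) else 1.0
    rd = _run("rediscretize", rediscretize_spatial, traj, q)
    simplified = _run("rdp", rdp_simplify, traj, params.rdp_epsilon)
    visits, revisits, lm_eff, _ = _run(
        "landmark_metrics", landmark_metrics, traj, env, params
    )
    return MeasureRow(
        subject_id=traj.subject_id,
        path_length=_run("path_length", path_length, traj),
        pausing=_run("pausing", pausing, traj, params),
        area_covered=_run("area_covered", area_covered, bins),
        roaming_entropy=_run("roaming_entropy", roaming_entropy, bins, env.k_norm),
        min_convex_polygon=_run("min_convex_polygon", min_convex_polygon, traj),
        fractal_dimension=_run("fractal_dimension", fractal_dimension, traj, params),
        sinuosity=_run("sinuosity", sinuosity, rd, params),
        landmark_visits=visits,
        landmark_revisits=revisits,
        revisiting=_run("revisiting", revisiting, traj, params),
        turnarounds=_run("turnarounds", turnarounds, traj, params),
        flight_turnarounds=_flight_turnarounds_simplified(simplified, params),
        area_efficiency=_run("area_efficiency", area_efficiency, bins),
        landmark_efficiency=lm_eff,
    )
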