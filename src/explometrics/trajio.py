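"""Trajectory, environment and results I/O.

All coordinates live in "virtual meters" (vm): one vm is one coordinate
unit of the environment, and no unit conversion is ever applied.
Trajectories are planar (x, y); loggers that record a vertical axis are
handled by mapping the two horizontal axes via ``column_map`` when
reading, so the core stays strictly two-dimensional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trajectory",
    "Landmark",
    "Environment",
    "MeasureParams",
    "MeasureRow",
    "MEASURE_COLUMNS",
    "TrajectoryFormatError",
    "DegenerateTrajectoryError",
    "ConfigError",
    "read_trajectory",
    "write_trajectory",
    "read_environment",
    "write_environment",
    "write_measure_table",
    "read_measure_table",
    "write_similarity_matrix",
    "write_merges_json",
    "write_heights_csv",
    "write_loadings_csv",
]


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file cannot be parsed as requested."""


class DegenerateTrajectoryError(ValueError):
    """Raised when a trajectory is too short or contains no movement."""


class ConfigError(ValueError):
    """Raised when an environment/parameter config is invalid."""


@dataclass
class Trajectory:
    """An ordered sequence of 2-D positions, optionally timestamped.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject/agent that produced the trajectory.
    points : (n, 2) float array
        Sample positions in vm, in logging order.
    times : (n,) float array, optional
        Timestamps in seconds, strictly increasing, aligned 1:1 with
        ``points``. Loggers without clocks leave this ``None`` and set
        ``sample_rate_hz`` instead.
    sample_rate_hz : float, optional
        Nominal sampling rate. Required by time-based measures when
        ``times`` is absent.
    """

    subject_id: str
    points: np.ndarray
    times: Optional[np.ndarray] = None
    sample_rate_hz: Optional[float] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise TrajectoryFormatError(
                f"{self.subject_id}: points must be an (n, 2) array, "
                f"got shape {self.points.shape}"
            )
        if len(self.points) < 2:
            raise DegenerateTrajectoryError(
                f"{self.subject_id}: a trajectory needs at least 2 points"
            )
        if not np.all(np.isfinite(self.points)):
            raise TrajectoryFormatError(
                f"{self.subject_id}: non-finite coordinates"
            )
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (len(self.points),):
                raise TrajectoryFormatError(
                    f"{self.subject_id}: times must align 1:1 with points"
                )
            if np.any(np.diff(self.times) <= 0):
                raise TrajectoryFormatError(
                    f"{self.subject_id}: times must be strictly increasing"
                )
        if self.sample_rate_hz is not None and self.sample_rate_hz <= 0:
            raise TrajectoryFormatError(
                f"{self.subject_id}: sample_rate_hz must be positive"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def effective_rate(self) -> Optional[float]:
        """Sampling rate: declared rate, else mean rate from timestamps."""
        if self.sample_rate_hz is not None:
            return self.sample_rate_hz
        if self.times is not None:
            span = self.times[-1] - self.times[0]
            if span > 0:
                return (len(self.points) - 1) / span
        return None

    def with_points(
        self,
        points: np.ndarray,
        times: Optional[np.ndarray] = None,
        sample_rate_hz: Optional[float] = None,
    ) -> "Trajectory":
        return Trajectory(
            subject_id=self.subject_id,
            points=points,
            times=times,
            sample_rate_hz=(
                sample_rate_hz if sample_rate_hz is not None else self.sample_rate_hz
            ),
        )


@dataclass(frozen=True)
class Landmark:
    id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ConfigError(f"landmark {self.id}: non-finite coordinates")


@dataclass
class Environment:
    """A bounded rectangular environment with a square occupancy grid.

    The grid is anchored at (xmin, ymin) with half-open square cells
    ``[x0 + i*s, x0 + (i+1)*s) x [y0 + j*s, y0 + (j+1)*s)``.  ``k_norm``
    is the entropy normalization constant: the number of grid cells the
    roaming-entropy denominator assumes reachable (typically the total
    number of cells of the environment, or the number of distinct cells
    explored by a whole cohort).
    """

    name: str
    bounds: tuple  # (xmin, ymin, xmax, ymax)
    bin_size: float
    k_norm: int
    landmarks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.bounds
        if not (xmax > xmin and ymax > ymin):
            raise ConfigError(f"{self.name}: bounds must satisfy xmax>xmin, ymax>ymin")
        if self.bin_size <= 0:
            raise ConfigError(f"{self.name}: bin_size must be positive")
        self.k_norm = int(self.k_norm)
        if self.k_norm < 1:
            raise ConfigError(f"{self.name}: k_norm must be >= 1")

    @property
    def n_cols(self) -> int:
        xmin, _, xmax, _ = self.bounds
        return int(np.ceil((xmax - xmin) / self.bin_size - 1e-12))

    @property
    def n_rows(self) -> int:
        _, ymin, _, ymax = self.bounds
        return int(np.ceil((ymax - ymin) / self.bin_size - 1e-12))

    @property
    def n_bins(self) -> int:
        return self.n_cols * self.n_rows


@dataclass
class MeasureParams:
    """Tunable parameters of the exploration measures.

    Defaults follow the free-exploration ("nemo") configuration: a
    landmark counts as visited within 20 vm, a place disc for revisiting
    has radius 14 vm, polyline simplification for flight-scale analysis
    uses epsilon = 6 vm and flight-scale turnarounds use a 160 degree
    cutoff, while step-scale turnarounds use the classic 180 degree
    cutoff.  ``rediscretize_step=None`` means "use the pooled median
    nonzero step length" (resolved by the pipeline before computing).
    """

    landmark_radius: float = 20.0
    revisit_radius: float = 14.0
    rediscretize_step: Optional[float] = None
    rdp_epsilon: float = 6.0
    flight_turn_cutoff: float = 160.0
    step_turn_cutoff: float = 180.0
    fd_n_steps: int = 20
    fd_min_factor: float = 0.5
    fd_max_factor: float = 10.0
    pause_epsilon: float = 1e-9
    target_hz: float = 10.0
    angle_tol: float = 0.5  # degrees of slack on the 180-degree step cutoff

    def __post_init__(self) -> None:
        positive = {
            "landmark_radius": self.landmark_radius,
            "revisit_radius": self.revisit_radius,
            "rdp_epsilon": self.rdp_epsilon,
            "pause_epsilon": self.pause_epsilon,
            "target_hz": self.target_hz,
        }
        if self.rediscretize_step is not None:
            positive["rediscretize_step"] = self.rediscretize_step
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if not (0 < self.flight_turn_cutoff <= 180):
            raise ConfigError("flight_turn_cutoff must be in (0, 180]")
        if not (0 < self.step_turn_cutoff <= 180):
            raise ConfigError("step_turn_cutoff must be in (0, 180]")
        if not self.fd_min_factor < self.fd_max_factor:
            raise ConfigError("fd_min_factor must be < fd_max_factor")
        if self.fd_n_steps < 3:
            raise ConfigError("fd_n_steps must be >= 3")


#: Canonical column order of the measures table (after subject_id).
MEASURE_COLUMNS = [
    "path_length",
    "pausing",
    "area_covered",
    "roaming_entropy",
    "min_convex_polygon",
    "fractal_dimension",
    "sinuosity",
    "landmark_visits",
    "landmark_revisits",
    "revisiting",
    "turnarounds",
    "flight_turnarounds",
    "area_efficiency",
    "landmark_efficiency",
]


@dataclass
class MeasureRow:
    """All exploration measures for one subject (one table row)."""

    subject_id: str
    path_length: float
    pausing: float
    area_covered: int
    roaming_entropy: float
    min_convex_polygon: float
    fractal_dimension: float
    sinuosity: float
    landmark_visits: int
    landmark_revisits: int
    revisiting: float
    turnarounds: int
    flight_turnarounds: int
    area_efficiency: float
    landmark_efficiency: float  # NaN when the subject enters no landmark

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_trajectory(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: str = ",",
    subject_id: Optional[str] = None,
    sample_rate_hz: Optional[float] = None,
) -> Trajectory:
    """Read a delimited trajectory file.

    ``column_map`` maps the roles ``x``, ``y`` and (optionally) ``time``
    to column names in the file, e.g. ``{"x": "X", "y": "Z"}`` for a
    game log whose horizontal plane is spanned by X and Z.  When no time
    role is mapped, a column named ``t`` or ``time`` is used if present.
    Rows are returned in file order; nothing is filtered or reordered.
    """
    path = Path(path)
    cmap = dict(column_map) if column_map else {}
    cmap.setdefault("x", "x")
    cmap.setdefault("y", "y")

    try:
        df = pd.read_csv(path, delimiter=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise TrajectoryFormatError(f"{path}: empty file") from exc

    for role in ("x", "y"):
        if cmap[role] not in df.columns:
            raise TrajectoryFormatError(
                f"{path}: missing column {cmap[role]!r} (role {role!r}); "
                f"available: {list(df.columns)}"
            )
    time_col = cmap.get("time")
    if time_col is not None and time_col not in df.columns:
        raise TrajectoryFormatError(
            f"{path}: missing column {time_col!r} (role 'time')"
        )
    if time_col is None:
        for candidate in ("t", "time"):
            if candidate in df.columns:
                time_col = candidate
                break

    def _numeric(col: str) -> np.ndarray:
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        raw_na = df[col].isna().to_numpy()
        bad = np.isnan(values) & ~raw_na
        if bad.any() or raw_na.any():
            row = int(np.argmax(bad | raw_na))
            raise TrajectoryFormatError(
                f"{path}: non-numeric value in column {col!r} at data row "
                f"{row + 1}: {df[col].iloc[row]!r}"
            )
        return values

    xy = np.column_stack([_numeric(cmap["x"]), _numeric(cmap["y"])])
    if len(xy) < 2:
        raise DegenerateTrajectoryError(f"{path}: fewer than 2 data rows")
    times = _numeric(time_col) if time_col is not None else None
    return Trajectory(
        subject_id=subject_id or path.stem,
        points=xy,
        times=times,
        sample_rate_hz=sample_rate_hz,
    )


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory as CSV with columns ``t,x,y`` (``x,y`` if untimed)."""
    path = Path(path)
    cols = {}
    if traj.times is not None:
        cols["t"] = traj.times
    cols["x"] = traj.x
    cols["y"] = traj.y
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    return path


def read_environment(path) -> tuple:
    """Read a YAML/JSON environment + parameters config.

    Required keys: ``bounds`` ([xmin, ymin, xmax, ymax]) and
    ``bin_size``.  Optional: ``name``, ``k_norm`` (defaults to the total
    number of grid cells inside the bounds), ``landmarks`` (list of
    ``{id, x, y}``) and ``params`` (any subset of ``MeasureParams``
    fields; the rest take their defaults).

    Returns
    -------
    (Environment, MeasureParams)
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a key/value document")
    for key in ("bounds", "bin_size"):
        if key not in doc:
            raise ConfigError(f"{path}: missing required key {key!r}")
    bounds = tuple(float(v) for v in doc["bounds"])
    if len(bounds) != 4:
        raise ConfigError(f"{path}: bounds must be [xmin, ymin, xmax, ymax]")
    bin_size = float(doc["bin_size"])
    if bin_size <= 0:
        raise ConfigError(f"{path}: bin_size must be positive")
    landmarks = [
        Landmark(id=str(lm["id"]), x=float(lm["x"]), y=float(lm["y"]))
        for lm in doc.get("landmarks", [])
    ]
    xmin, ymin, xmax, ymax = bounds
    default_k = int(np.ceil((xmax - xmin) / bin_size - 1e-12)) * int(
        np.ceil((ymax - ymin) / bin_size - 1e-12)
    )
    env = Environment(
        name=str(doc.get("name", path.stem)),
        bounds=bounds,
        bin_size=bin_size,
        k_norm=int(doc.get("k_norm", default_k)),
        landmarks=landmarks,
    )
    raw_params = doc.get("params", {}) or {}
    known = {f.name for f in fields(MeasureParams)}
    unknown = set(raw_params) - known
    if unknown:
        raise ConfigError(f"{path}: unknown params {sorted(unknown)}")
    params = MeasureParams(**raw_params)
    return env, params


def write_environment(env: Environment, params: MeasureParams, path) -> Path:
    doc = {
        "name": env.name,
        "bounds": [float(v) for v in env.bounds],
        "bin_size": float(env.bin_size),
        "k_norm": int(env.k_norm),
        "landmarks": [
            {"id": lm.id, "x": float(lm.x), "y": float(lm.y)} for lm in env.landmarks
        ],
        "params": {
            f.name: getattr(params, f.name)
            for f in fields(MeasureParams)
            if getattr(params, f.name) is not None
        },
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def write_measure_table(rows: Sequence[MeasureRow], path) -> Path:
    """Write one CSV row per subject with the canonical column order."""
    if not rows:
        raise ValueError("write_measure_table: empty list of rows")
    ids = [r.subject_id for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject_id(s): {dupes}")
    df = pd.DataFrame([r.as_dict() for r in rows])
    df = df[["subject_id"] + MEASURE_COLUMNS]
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_measure_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ["subject_id"] + MEASURE_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing measure columns {missing}")
    return df


def write_similarity_matrix(sim: pd.DataFrame, path) -> Path:
    path = Path(path)
    sim.to_csv(path, float_format="%.17g")
    return path


def write_merges_json(merges, path) -> Path:
    """Write a cluster merge history as ``[[members_a, members_b, height], ...]``."""
    payload = [
        [sorted(a), sorted(b), float(h)] for a, b, h in merges
    ]
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def write_heights_csv(heights, path) -> Path:
    """Aggregation heights vs. the number of clusters each merge leaves."""
    n = len(heights) + 1
    df = pd.DataFrame(
        {
            "n_clusters": np.arange(n - 1, 0, -1),
            "height": np.asarray(heights, dtype=float),
        }
    )
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def write_loadings_csv(loadings: pd.DataFrame, assignment: Mapping[str, int], path) -> Path:
    """Loadings table (variables x clusters) with an own-cluster flag column."""
    out = loadings.copy()
    out["own_cluster"] = [assignment[v] for v in out.index]
    path = Path(path)
    out.to_csv(path, float_format="%.17g")
    return path
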