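"""Synthetic environments, agent cohorts and analytic fixtures.

The simulator emulates fixed-speed sampled movement in a bounded
environment: a correlated random walk with approximately constant
nonzero step lengths at a nominal sampling rate, occasional zero-length
pause samples, wrapped-normal turning noise, sporadic dead-end
reversals, a revisiting pull toward previously visited grid cells and
an attraction toward unvisited landmarks.  Every trajectory is fully
reproducible from (cohort seed, agent seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from ._kernels import walk_core
from .trajio import Environment, Landmark, Trajectory

__all__ = [
    "TraitProfile",
    "SimConfig",
    "make_environment",
    "simulate_agent",
    "simulate_cohort",
    "default_trait_sampler",
    "three_trait_sampler",
    "fixtures",
]


@dataclass
class TraitProfile:
    """Latent behavioral traits of a simulated agent.

    activity
        Pause probability per sample, in [0, 1] (higher = more pausing,
        i.e. *less* locomotor activity).
    tortuosity
        Standard deviation of the wrapped-normal turning noise, in
        radians per step.
    turnaround_rate
        Per-sample probability of initiating a dead-end turnaround,
        executed as a tight smooth U-turn (pi / uturn_steps radians per
        sample; with the default 18 samples the turn diameter is about
        5.5 vm, under the flight-scale epsilon of 6): a full reversal
        at flight scale, smooth at step scale.
    revisit_bias
        Weight (>= 0) pulling the heading toward the nearest previously
        visited grid-cell center.
    landmark_attraction
        Weight (>= 0) pulling the heading toward the nearest unvisited
        landmark.
    """

    activity: float = 0.1
    tortuosity: float = 0.2
    turnaround_rate: float = 0.0
    revisit_bias: float = 0.0
    landmark_attraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.activity <= 1:
            raise ValueError("activity must be in [0, 1]")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be >= 0")
        if not 0 <= self.turnaround_rate <= 1:
            raise ValueError("turnaround_rate must be in [0, 1]")
        if self.revisit_bias < 0 or self.landmark_attraction < 0:
            raise ValueError("bias weights must be >= 0")


@dataclass
class SimConfig:
    """Cohort-level simulation settings.

    Defaults mirror a short free-exploration session: 150 s at 10 Hz
    with a fixed movement speed of 0.48 vm per sample.
    """

    env: Environment
    n_agents: int = 1
    duration_s: float = 150.0
    hz: float = 10.0
    step_vm: float = 0.48
    trait_sampler: Optional[Callable[[np.random.Generator], TraitProfile]] = None
    seed: int = 0
    #: samples a dead-end U-turn is spread over (pi / uturn_steps per sample)
    uturn_steps: int = 18
    #: relative sd of per-step speed jitter (frame-timing noise of
    #: fixed-speed loggers; steps are approximately, not exactly, constant)
    speed_jitter: float = 0.01

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.hz <= 0 or self.step_vm <= 0:
            raise ValueError("duration_s, hz and step_vm must be positive")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")


def make_environment(
    width: float,
    height: float,
    bin_size: float,
    n_landmarks: int = 0,
    layout: str = "grid",
    seed: int = 0,
) -> Environment:
    """Deterministic rectangular environment with landmarks at layout nodes.

    Layouts: ``grid`` spreads landmarks on a regular lattice (evenly
    distributed points of interest), ``comb`` places them at the tips of
    parallel dead-end corridors, ``loop`` on a ring (street networks
    with loops).  ``k_norm`` is the total number of grid cells inside
    the bounds.
    """
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    if bin_size > min(width, height):
        raise ValueError("bin_size must not exceed the smaller dimension")
    if n_landmarks < 0:
        raise ValueError("n_landmarks must be >= 0")
    ncols = int(np.ceil(width / bin_size - 1e-12))
    nrows = int(np.ceil(height / bin_size - 1e-12))
    rng = np.random.default_rng(seed)
    positions: List[Tuple[float, float]] = []
    if n_landmarks:
        if layout == "grid":
            g = int(math.ceil(math.sqrt(n_landmarks)))
            xs = (np.arange(g) + 0.5) / g * width
            ys = (np.arange(g) + 0.5) / g * height
            for j in range(g):
                for i in range(g):
                    positions.append((float(xs[i]), float(ys[j])))
        elif layout == "comb":
            xs = (np.arange(n_landmarks) + 0.5) / n_landmarks * width
            positions = [(float(x), 0.85 * height) for x in xs]
        elif layout == "loop":
            radius = 0.35 * min(width, height)
            angles = 2 * np.pi * np.arange(n_landmarks) / n_landmarks
            positions = [
                (width / 2 + radius * math.cos(a), height / 2 + radius * math.sin(a))
                for a in angles
            ]
        else:
            raise ValueError(f"unknown layout {layout!r}")
        positions = positions[:n_landmarks]
        jitter = rng.uniform(-0.05, 0.05, size=(n_landmarks, 2)) * bin_size
        positions = [
            (
                float(np.clip(x + jitter[i, 0], 0, width)),
                float(np.clip(y + jitter[i, 1], 0, height)),
            )
            for i, (x, y) in enumerate(positions)
        ]
    landmarks = [Landmark(id=f"L{i:02d}", x=x, y=y) for i, (x, y) in enumerate(positions)]
    return Environment(
        name=f"synthetic_{layout}",
        bounds=(0.0, 0.0, float(width), float(height)),
        bin_size=float(bin_size),
        k_norm=ncols * nrows,
        landmarks=landmarks,
    )


def _agent_rng(seed: int, agent_seed: int) -> np.random.Generator:
    # fixed counter scheme: one master seed, one per-agent counter
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, int(agent_seed)])


def simulate_agent(
    profile: TraitProfile, config: SimConfig, agent_seed: int
) -> Trajectory:
    """One correlated-random-walk agent; bit-reproducible from the seeds."""
    env = config.env
    n = int(round(config.duration_s * config.hz))
    rng = _agent_rng(config.seed, agent_seed)
    xmin, ymin, xmax, ymax = env.bounds
    x0 = float(rng.uniform(xmin + 0.3 * (xmax - xmin), xmin + 0.7 * (xmax - xmin)))
    y0 = float(rng.uniform(ymin + 0.3 * (ymax - ymin), ymin + 0.7 * (ymax - ymin)))
    h0 = float(rng.uniform(-np.pi, np.pi))
    pause_u = rng.uniform(size=n - 1)
    rev_u = rng.uniform(size=n - 1)
    noise = rng.normal(0.0, profile.tortuosity, size=n - 1)
    # per-agent jitter scale emulates heterogeneous logging hardware
    agent_jitter = config.speed_jitter * rng.uniform(0.5, 2.0)
    step_mult = np.clip(1.0 + agent_jitter * rng.normal(size=n - 1), 0.2, 5.0)
    lmx = np.array([lm.x for lm in env.landmarks], dtype=float)
    lmy = np.array([lm.y for lm in env.landmarks], dtype=float)
    pts = walk_core(
        n,
        float(config.step_vm),
        x0,
        y0,
        h0,
        pause_u,
        rev_u,
        noise,
        step_mult,
        float(profile.activity),
        float(profile.turnaround_rate),
        float(profile.revisit_bias),
        float(profile.landmark_attraction),
        lmx,
        lmy,
        20.0,
        float(xmin),
        float(ymin),
        float(xmax),
        float(ymax),
        float(env.bin_size),
        int(config.uturn_steps),
        float(np.pi / config.uturn_steps),
    )
    return Trajectory(
        subject_id=f"agent{agent_seed:04d}",
        points=pts,
        times=np.arange(n) / config.hz,
        sample_rate_hz=config.hz,
    )


def default_trait_sampler(rng: np.random.Generator) -> TraitProfile:
    """A broad, realistic cohort: all traits vary independently."""
    return TraitProfile(
        activity=float(rng.uniform(0.05, 0.45)),
        tortuosity=float(rng.uniform(0.02, 0.2)),
        turnaround_rate=float(rng.uniform(0.0, 0.01)),
        revisit_bias=float(rng.uniform(0.0, 0.3)),
        landmark_attraction=float(rng.uniform(0.0, 0.4)),
    )


def three_trait_sampler(rng: np.random.Generator) -> TraitProfile:
    """Three strongly separated independent latent traits.

    Latent 1 (activity) drives pausing/locomotion; latent 2
    (tortuosity) drives path shape; latent 3 (inefficiency) jointly
    drives the revisiting pull and the dead-end reversal rate, the two
    mechanisms behind inefficient exploration.  Landmark attraction is
    off so landmark measures stay out of the trait structure.
    """
    u_act = rng.uniform()
    u_tor = rng.uniform()
    u_rev = rng.uniform()
    return TraitProfile(
        activity=0.75 * u_act,
        tortuosity=0.06 + 0.22 * u_tor,
        turnaround_rate=0.012 * u_rev,
        revisit_bias=0.05 * u_rev,
        landmark_attraction=0.0,
    )


def simulate_cohort(config: SimConfig) -> Tuple[List[Trajectory], List[TraitProfile]]:
    """Independent agents with traits drawn from the trait sampler.

    Traits come from a dedicated stream so cohorts share a prefix when
    only ``n_agents`` changes.  Returns the trajectories and the
    ground-truth traits (for recovery experiments).
    """
    sampler = config.trait_sampler or default_trait_sampler
    trait_rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 987654321])
    trajectories, profiles = [], []
    for i in range(config.n_agents):
        profile = sampler(trait_rng)
        trajectories.append(simulate_agent(profile, config, agent_seed=i))
        profiles.append(profile)
    return trajectories, profiles


# ---------------------------------------------------------------------------
# Analytic fixtures
# ---------------------------------------------------------------------------


def _traj(name: str, pts: np.ndarray, hz: float = 10.0) -> Trajectory:
    return Trajectory(
        subject_id=name,
        points=np.asarray(pts, dtype=float),
        times=np.arange(len(pts)) / hz,
        sample_rate_hz=hz,
    )


def comb_trajectory(
    n_teeth: int = 5,
    tooth_length: float = 40.0,
    spacing: float = 30.0,
    step: float = 0.5,
    jitter: float = 0.8,
) -> Trajectory:
    """A comb-shaped path: dead-end corridors walked up and back.

    Each tooth produces exactly one full reversal at its tip; a lateral
    sinusoidal jitter (amplitude < epsilon/4 for the default epsilon=6)
    perturbs every step so no raw turning angle hits 180 degrees
    exactly, while the flight-scale structure is untouched.
    """
    xs: List[float] = []
    ys: List[float] = []
    # without jitter the descent retraces the ascent exactly (step-scale
    # reversals of precisely 180 degrees); with jitter a small lateral
    # offset keeps ascent and descent from coinciding
    off = 0.35 if jitter > 0 else 0.0
    for tooth in range(n_teeth):
        bx = tooth * spacing
        n_up = int(round(tooth_length / step))
        for i in range(n_up + 1):
            xs.append(bx)
            ys.append(i * step)
        for i in range(n_up - 1, -1, -1):
            xs.append(bx + off)
            ys.append(i * step)
        if tooth < n_teeth - 1:
            n_base = int(round(spacing / step))
            for i in range(1, n_base):
                xs.append(bx + i * step)
                ys.append(0.0)
    pts = np.column_stack([xs, ys]).astype(float)
    # deterministic sub-epsilon jitter, perpendicular-ish, never zero-step
    t = np.arange(len(pts))
    pts[:, 0] += jitter * np.sin(0.9 * t + 0.3)
    pts[:, 1] += jitter * np.sin(1.3 * t + 1.1)
    return _traj("comb_5_teeth", pts)


def fixtures(seed: int = 0) -> Dict[str, Trajectory]:
    """A deterministic library of analytic test trajectories."""
    out: Dict[str, Trajectory] = {}

    n = 201
    out["straight_line"] = _traj(
        "straight_line", np.column_stack([np.linspace(0, 100, n), np.zeros(n)])
    )

    side = np.linspace(0, 1, 11)
    square = np.concatenate(
        [
            np.column_stack([side, np.zeros(11)]),
            np.column_stack([np.ones(10), side[1:]]),
            np.column_stack([side[::-1][1:], np.ones(10)]),
            np.column_stack([np.zeros(10), side[::-1][1:]]),
        ]
    )
    out["unit_square_loop"] = _traj("unit_square_loop", square)

    out["comb_5_teeth"] = comb_trajectory()

    angles = np.linspace(0, 2 * np.pi, 721)
    out["circle"] = _traj(
        "circle",
        np.column_stack([50 * np.cos(angles) + 60, 50 * np.sin(angles) + 60]),
    )

    fwd = np.linspace(0, 100, 201)
    out["out_and_back"] = _traj(
        "out_and_back",
        np.column_stack([np.concatenate([fwd, fwd[::-1][1:]]),
                         np.zeros(401)]),
    )

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 424242])
    heading = np.cumsum(rng.normal(0, 0.6, size=2000))
    steps = np.column_stack([0.5 * np.cos(heading), 0.5 * np.sin(heading)])
    walk = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    out["dense_random_walk"] = _traj("dense_random_walk", walk)

    return out
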