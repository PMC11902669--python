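"""Kinematic random-walk simulator for a wheeled agent in a square enclosure.

The agent moves continuously forward at a fixed speed while receiving one of a
small discrete set of yaw-rate commands per step.  A look-ahead rule biases the
command distribution away from the walls so trajectories stay collision-free
while still covering the arena roughly uniformly.  This is a lightweight
stand-in for a full physics simulation: no mass, slip or actuation delay.

Coordinate convention: origin at the arena centre, x to the right, y up,
heading measured counter-clockwise from +x in radians, wrapped to (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

__all__ = [
    "ArenaConfig",
    "Pose",
    "Trajectory",
    "InvalidActionError",
    "wrap_angle",
    "action_to_rate",
    "sample_start",
    "step",
    "sample_action",
    "generate_trajectory",
    "trajectory_rng",
    "egocentric_inputs",
]

_TWO_PI = 2.0 * np.pi


class InvalidActionError(ValueError):
    """Raised when an action index is outside the discrete command set."""


def wrap_angle(theta):
    """Wrap an angle (or array of angles) to the interval (-pi, pi]."""
    wrapped = ((np.asarray(theta) + np.pi) % _TWO_PI) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return float(wrapped) if np.ndim(theta) == 0 else wrapped


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry, kinematics and command set of the bounded arena.

    The defaults describe a 6.4 m square enclosure explored in episodes of 100
    steps that start from a random pose inside the central 2.1 x 2.1 m region,
    with seven yaw-rate commands spanning -2.25 .. +2.25 rad/s in 0.75 rad/s
    increments and constant forward motion.
    """

    half_width: float = 3.2
    start_half_width: float = 1.05
    wall_margin: float = 0.30
    n_steps: int = 100
    dt: float = 0.5
    forward_speed: float = 0.4
    action_min: float = -2.25
    action_increment: float = 0.75
    n_actions: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        top = self.action_min + (self.n_actions - 1) * self.action_increment
        if not np.isclose(top, -self.action_min):
            raise ValueError(
                "action set must be symmetric: "
                f"max action {top} != -action_min {-self.action_min}"
            )
        if not 0.0 < self.start_half_width < self.half_width:
            raise ValueError("start region must be inside the arena")
        if not 0.0 <= self.wall_margin < self.half_width:
            raise ValueError("wall_margin must be smaller than half_width")
        if self.n_steps < 1 or self.n_actions < 1:
            raise ValueError("n_steps and n_actions must be positive")

    @property
    def actions(self) -> np.ndarray:
        """The full yaw-rate command set (rad/s), in index order."""
        return self.action_min + np.arange(self.n_actions) * self.action_increment

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Pose:
    """Planar position (m) plus heading (rad, wrapped to (-pi, pi])."""

    x: float
    y: float
    heading: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Trajectory:
    """One simulated episode.

    ``poses`` has shape (n_steps + 1, 3) with columns (x, y, heading);
    ``linear_speeds`` and ``angular_rates`` record the command actually
    applied at each of the n_steps transitions.
    """

    poses: np.ndarray
    linear_speeds: np.ndarray
    angular_rates: np.ndarray
    actions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.poses = np.asarray(self.poses, dtype=float)
        self.linear_speeds = np.asarray(self.linear_speeds, dtype=float)
        self.angular_rates = np.asarray(self.angular_rates, dtype=float)
        if self.poses.shape[0] != self.linear_speeds.shape[0] + 1:
            raise ValueError("need exactly one more pose than transitions")
        if self.linear_speeds.shape != self.angular_rates.shape:
            raise ValueError("speed and rate records must align")

    @property
    def n_steps(self) -> int:
        return self.linear_speeds.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return self.poses[:, :2]

    @property
    def headings(self) -> np.ndarray:
        return self.poses[:, 2]

    def iter_poses(self) -> Iterator[Pose]:
        for x, y, h in self.poses:
            yield Pose(x, y, h)


def action_to_rate(index: int, cfg: ArenaConfig) -> float:
    """Map a discrete action index to its yaw rate (rad/s)."""
    if not 0 <= index < cfg.n_actions:
        raise InvalidActionError(
            f"action index {index} outside [0, {cfg.n_actions})"
        )
    return cfg.action_min + index * cfg.action_increment


def sample_start(rng: np.random.Generator, cfg: ArenaConfig) -> Pose:
    """Draw a uniform random pose from the central start region."""
    x, y = rng.uniform(-cfg.start_half_width, cfg.start_half_width, size=2)
    heading = np.pi - rng.uniform(0.0, _TWO_PI)  # uniform on (-pi, pi]
    return Pose(float(x), float(y), float(heading))


def step(pose: Pose, action: int, cfg: ArenaConfig) -> Pose:
    """Apply one command: turn for dt at the commanded rate, then translate.

    The heading update precedes the translation (turn-then-move), matching a
    commanded-velocity controller executed over a single control interval.
    The position is clamped to the walls as a safety net; the sampling policy
    in :func:`sample_action` is responsible for making the clamp a no-op.
    """
    rate = action_to_rate(action, cfg)
    heading = wrap_angle(pose.heading + rate * cfg.dt)
    d = cfg.forward_speed * cfg.dt
    x = float(np.clip(pose.x + d * np.cos(heading), -cfg.half_width, cfg.half_width))
    y = float(np.clip(pose.y + d * np.sin(heading), -cfg.half_width, cfg.half_width))
    return Pose(x, y, heading)


def sample_action(rng: np.random.Generator, pose: Pose, cfg: ArenaConfig) -> int:
    """Draw the next command, avoiding wall collisions.

    If the straight-ahead look-ahead point keeps at least ``wall_margin``
    clearance from every wall, the command is uniform over the whole action
    set.  Otherwise only commands whose resulting heading turns toward the
    arena centre are eligible; if the agent already faces the centre as well
    as possible, the closest-turning commands are used.

    The look-ahead horizon is the number of steps a full heading reversal
    takes at the maximum yaw rate: triggering the avoidance turn any later
    can strand the agent in a corner with too little room to swing away from
    the walls no matter which command it picks.
    """
    d = cfg.forward_speed * cfg.dt
    turn_per_step = abs(cfg.action_min) * cfg.dt
    horizon = int(np.ceil(np.pi / turn_per_step))
    look_x = pose.x + horizon * d * np.cos(pose.heading)
    look_y = pose.y + horizon * d * np.sin(pose.heading)
    clearance = cfg.half_width - max(abs(look_x), abs(look_y))
    if clearance >= cfg.wall_margin:
        return int(rng.integers(cfg.n_actions))

    bearing = np.arctan2(-pose.y, -pose.x)  # direction of the arena centre
    current_off = abs(wrap_angle(pose.heading - bearing))
    new_headings = wrap_angle(pose.heading + cfg.actions * cfg.dt)
    offsets = np.abs(wrap_angle(new_headings - bearing))
    toward = offsets < current_off - 1e-12
    if not toward.any():
        toward = offsets == offsets.min()
    # among the centre-turning commands, prefer those that keep clearance;
    # a large turn can reduce the angular offset yet overshoot into the wall
    next_x = pose.x + d * np.cos(new_headings)
    next_y = pose.y + d * np.sin(new_headings)
    next_clear = cfg.half_width - np.maximum(np.abs(next_x), np.abs(next_y))
    safe = toward & (next_clear >= cfg.wall_margin)
    if not safe.any():
        best = next_clear[toward].max()
        safe = toward & (next_clear >= best - 1e-12)
    return int(rng.choice(np.flatnonzero(safe)))


def trajectory_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent per-trajectory random stream from (master seed, index)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    )


def generate_trajectory(
    cfg: ArenaConfig, rng: np.random.Generator | None = None
) -> Trajectory:
    """Simulate one collision-free episode of ``cfg.n_steps`` transitions."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pose = sample_start(rng, cfg)
    poses = np.empty((cfg.n_steps + 1, 3))
    actions = np.empty(cfg.n_steps, dtype=np.int64)
    rates = np.empty(cfg.n_steps)
    poses[0] = (pose.x, pose.y, pose.heading)
    for t in range(cfg.n_steps):
        a = sample_action(rng, pose, cfg)
        pose = step(pose, a, cfg)
        poses[t + 1] = (pose.x, pose.y, pose.heading)
        actions[t] = a
        rates[t] = action_to_rate(a, cfg)
    speeds = np.full(cfg.n_steps, cfg.forward_speed)
    return Trajectory(poses, speeds, rates, actions)


def egocentric_inputs(traj: Trajectory) -> np.ndarray:
    """Self-motion input triples (v_t, sin(phi_t), cos(phi_t)) per step.

    v_t is the egocentric linear speed and phi_t the yaw-rate command applied
    at step t; together the triple is the only information the network
    receives about the agent's motion.
    """
    return np.column_stack(
        (traj.linear_speeds, np.sin(traj.angular_rates), np.cos(traj.angular_rates))
    )
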