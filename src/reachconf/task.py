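"""Task geometry, reward function, and the capture rule.

The reach-and-report task: an observer reaches from a start annulus toward a
visual target and afterwards reports confidence by setting the radius of a
circle centered on the target.  A trial is rewarded when that circle captures
the dot marking the true reach endpoint; the reward decreases linearly with
circle radius, so tight circles are worth more but risk missing.

All coordinates are in millimetres, origin at the center of the start annulus,
with +y pointing from the start toward straight-ahead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Point",
    "RewardSpec",
    "TaskGeometry",
    "DEFAULT_REWARD",
    "DEFAULT_GEOMETRY",
    "reward",
    "capture",
    "target_position",
    "max_points_for_endpoint",
]

#: A point in task coordinates: any (2,) array-like of finite floats, in mm.
Point = np.ndarray


def as_point(p) -> np.ndarray:
    """Coerce to a finite (2,) float array."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (2,):
        raise ValueError(f"expected a 2-D point, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite point coordinates: {arr}")
    return arr


@dataclass(frozen=True)
class RewardSpec:
    """Linear ramp from ``max_points`` down to zero points.

    Circles of radius ``full_radius`` or less earn ``max_points``; circles of
    radius ``zero_radius`` or more earn nothing; in between the reward falls
    linearly.
    """

    max_points: float = 10.0
    full_radius: float = 2.5
    zero_radius: float = 70.0

    def __post_init__(self):
        if not (0 < self.full_radius < self.zero_radius):
            raise ValueError("require 0 < full_radius < zero_radius")
        if self.max_points <= 0:
            raise ValueError("max_points must be positive")


@dataclass(frozen=True)
class TaskGeometry:
    """Spatial layout of both tasks.

    ``sector_angles_deg`` are the six nominal target directions on the main
    task's arc (90 deg = straight ahead); targets get isotropic Gaussian
    jitter with per-axis SD ``jitter_sd``.  The control task uses a single
    target straight ahead at ``control_target_distance``.  The endpoint is
    displayed as a dot of radius ``endpoint_dot_radius``; the capture rule
    tests overlap between the confidence circle and that dot.
    """

    control_target_distance: float = 150.0
    arc_radius: float = 183.0
    sector_angles_deg: tuple = (15.0, 45.0, 75.0, 105.0, 135.0, 165.0)
    jitter_sd: float = 15.0
    endpoint_dot_radius: float = 2.25
    start: tuple = (0.0, 0.0)

    def __post_init__(self):
        angles = np.asarray(self.sector_angles_deg, dtype=float)
        if not np.all(np.diff(angles) > 0):
            raise ValueError("sector angles must be strictly increasing")
        if not np.all((angles > 0) & (angles < 180)):
            raise ValueError("sector angles must lie in (0, 180) degrees")
        for name in ("control_target_distance", "arc_radius", "jitter_sd",
                     "endpoint_dot_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_sectors(self) -> int:
        return len(self.sector_angles_deg)

    @property
    def control_target(self) -> np.ndarray:
        """Control-task target: straight ahead of the start location."""
        return np.asarray(self.start, float) + np.array(
            [0.0, self.control_target_distance])


DEFAULT_REWARD = RewardSpec()
DEFAULT_GEOMETRY = TaskGeometry()


def reward(radius, spec: RewardSpec = DEFAULT_REWARD):
    """Points earned by a capturing confidence circle of the given radius.

    Vectorized over ``radius``.  Raises on negative radii.
    """
    r = np.asarray(radius, dtype=float)
    if np.any(r < 0):
        raise ValueError("circle radius must be non-negative")
    ramp = spec.max_points * (spec.zero_radius - r) / (
        spec.zero_radius - spec.full_radius)
    out = np.clip(ramp, 0.0, spec.max_points)
    return out if out.ndim else float(out)


def capture(distance, circle_radius, geometry: TaskGeometry = DEFAULT_GEOMETRY):
    """Whether a circle of ``circle_radius`` around the target captures an
    endpoint at ``distance`` from the target.

    The circle wins if it intersects or encloses the endpoint dot, i.e. the
    center-to-center distance does not exceed circle radius + dot radius.
    Vectorized over both arguments.
    """
    d = np.asarray(distance, dtype=float)
    r = np.asarray(circle_radius, dtype=float)
    if np.any(d < 0) or np.any(r < 0):
        raise ValueError("distance and circle_radius must be non-negative")
    out = d <= r + geometry.endpoint_dot_radius
    return out if out.ndim else bool(out)


def target_position(sector_index: int, jitter,
                    geometry: TaskGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Jittered main-task target location for one of the six arc sectors."""
    if not 0 <= sector_index < geometry.n_sectors:
        raise ValueError(
            f"sector_index must be in [0, {geometry.n_sectors - 1}]")
    theta = np.deg2rad(geometry.sector_angles_deg[sector_index])
    base = geometry.arc_radius * np.array([np.cos(theta), np.sin(theta)])
    return np.asarray(geometry.start, float) + base + as_point(jitter)


def max_points_for_endpoint(distance, spec: RewardSpec = DEFAULT_REWARD,
                            geometry: TaskGeometry = DEFAULT_GEOMETRY):
    """Best attainable score for an endpoint at ``distance`` from the target:
    the reward of the smallest circle that still captures it."""
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    smallest = np.maximum(0.0, d - geometry.endpoint_dot_radius)
    return reward(smallest, spec)
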