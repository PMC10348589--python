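"""Generative model of the two behavioral tasks.

Simulates observers performing the control motor-awareness task (reach, then
indicate the perceived endpoint) and the main confidence-judgment task
(triplets of two feedback reaches followed by one confidence report), and
samples observer parameters from log-normal priors for recovery studies.

Trial tables are plain pandas DataFrames in the column layout written to CSV;
latent sensed locations are retained in simulation output (they are never
available for real data) so tests can check the generative chain directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observers import (DEFAULT_SEARCH, ModelKind, ObserverParams,
                        SearchConfig, optimal_circle_radial, radial_belief)
from .task import (DEFAULT_GEOMETRY, DEFAULT_REWARD, RewardSpec, TaskGeometry,
                   target_position)

__all__ = [
    "LogNormalSpec",
    "ParamPrior",
    "CONTROL_COLUMNS",
    "MAIN_COLUMNS",
    "sample_parameters",
    "simulate_control_task",
    "simulate_main_task",
    "write_control_csv",
    "write_main_csv",
]

CONTROL_COLUMNS = ["trial", "target_x", "target_y", "endpoint_x", "endpoint_y",
                   "indicated_x", "indicated_y", "sensed_x", "sensed_y"]
MAIN_COLUMNS = ["session", "triplet", "triplet_position", "sector",
                "target_x", "target_y", "endpoint_x", "endpoint_y", "kind",
                "circle_radius", "sensed_x", "sensed_y"]


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal distribution parameterized by its arithmetic mean and
    variance (the moments of the distribution itself, not of the log)."""

    mean: float
    var: float

    def __post_init__(self):
        if self.mean <= 0 or self.var <= 0:
            raise ValueError("log-normal mean and variance must be positive")

    @property
    def log_var(self) -> float:
        return float(np.log1p(self.var / self.mean**2))

    @property
    def log_mean(self) -> float:
        return float(np.log(self.mean) - 0.5 * self.log_var)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.lognormal(self.log_mean, np.sqrt(self.log_var), size)


@dataclass(frozen=True)
class ParamPrior:
    """Per-parameter log-normal priors used for recovery simulations.

    The default moments are sigma_m: (20, 25), sigma_p: (35, 400),
    sigma_s: (7, 25), all in mm / mm^2.  Alternative presets move the
    sigma_p prior to mean 40 or 20 with variance 200.
    """

    sigma_m: LogNormalSpec = LogNormalSpec(20.0, 25.0)
    sigma_p: LogNormalSpec = LogNormalSpec(35.0, 400.0)
    sigma_s: LogNormalSpec = LogNormalSpec(7.0, 25.0)

    @classmethod
    def default(cls) -> "ParamPrior":
        return cls()

    @classmethod
    def wide_sigma_p(cls) -> "ParamPrior":
        return cls(sigma_p=LogNormalSpec(40.0, 200.0))

    @classmethod
    def narrow_sigma_p(cls) -> "ParamPrior":
        return cls(sigma_p=LogNormalSpec(20.0, 200.0))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_parameters(n_sets: int, prior: ParamPrior | None = None,
                      seed=None) -> list[ObserverParams]:
    """Draw i.i.d. observer parameter sets from the prior."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    prior = prior or ParamPrior()
    rng = _as_rng(seed)
    sm = prior.sigma_m.sample(rng, n_sets)
    sp = prior.sigma_p.sample(rng, n_sets)
    ss = prior.sigma_s.sample(rng, n_sets)
    return [ObserverParams(m, p, s) for m, p, s in zip(sm, sp, ss)]


def simulate_control_task(params: ObserverParams, n_trials: int = 300,
                          geometry: TaskGeometry = DEFAULT_GEOMETRY,
                          seed=None) -> pd.DataFrame:
    """Simulate the control motor-awareness task.

    The target sits straight ahead on every trial.  Endpoints scatter around
    it with SD sigma_m, the sensed location around the endpoint with SD
    sigma_p, and the indicated endpoint is the MAP combination of target and
    sensed location.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _as_rng(seed)
    t = geometry.control_target
    e = t + rng.normal(0.0, params.sigma_m, (n_trials, 2))
    p = e + rng.normal(0.0, params.sigma_p, (n_trials, 2))
    w = params.w_p
    i = w * p + (1.0 - w) * t
    return pd.DataFrame({
        "trial": np.arange(1, n_trials + 1),
        "target_x": t[0], "target_y": t[1],
        "endpoint_x": e[:, 0], "endpoint_y": e[:, 1],
        "indicated_x": i[:, 0], "indicated_y": i[:, 1],
        "sensed_x": p[:, 0], "sensed_y": p[:, 1],
    })


def _sector_sequence(n_trials: int, n_sectors: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Each sector appears exactly once in every consecutive block of
    ``n_sectors`` trials, in random order within the block."""
    n_blocks = int(np.ceil(n_trials / n_sectors))
    seq = np.concatenate([rng.permutation(n_sectors) for _ in range(n_blocks)])
    return seq[:n_trials]


def simulate_main_task(model: ModelKind, params: ObserverParams,
                       n_triplets: int = 300,
                       geometry: TaskGeometry = DEFAULT_GEOMETRY,
                       reward_spec: RewardSpec = DEFAULT_REWARD,
                       seed=None, n_sessions: int = 3,
                       search: SearchConfig = DEFAULT_SEARCH,
                       convention: str = "weighted") -> pd.DataFrame:
    """Simulate the main confidence-judgment task for one observer.

    Trials come in triplets (two feedback reaches, then one confidence
    report), with targets cycling over the six jittered arc sectors.  On
    confidence trials the observer senses the endpoint, sets the
    expected-gain-optimal circle for its model, and the setting is perturbed
    by Gaussian noise (redrawn until non-negative).
    """
    if n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    model = ModelKind(model)
    rng = _as_rng(seed)
    n_trials = 3 * n_triplets
    sectors = _sector_sequence(n_trials, geometry.n_sectors, rng)
    jitter = rng.normal(0.0, geometry.jitter_sd, (n_trials, 2))
    targets = np.stack([target_position(s, j, geometry)
                        for s, j in zip(sectors, jitter)])
    endpoints = targets + rng.normal(0.0, params.sigma_m, (n_trials, 2))

    triplet = np.repeat(np.arange(1, n_triplets + 1), 3)
    position = np.tile([1, 2, 3], n_triplets)
    is_conf = position == 3
    per_session = int(np.ceil(n_triplets / n_sessions))
    session = 1 + (triplet - 1) // per_session

    sensed = np.full((n_trials, 2), np.nan)
    circle = np.full(n_trials, np.nan)
    p = endpoints[is_conf] + rng.normal(0.0, params.sigma_p,
                                        (int(is_conf.sum()), 2))
    sensed[is_conf] = p
    d = np.linalg.norm(p - targets[is_conf], axis=1)
    nu, sd = radial_belief(model, d, params, convention)
    c_opt = optimal_circle_radial(nu, sd, reward_spec, geometry, search,
                                  refine=True)
    c = c_opt + rng.normal(0.0, params.sigma_s, c_opt.shape)
    while np.any(c < 0):  # physical radii are non-negative: redraw the noise
        bad = c < 0
        c[bad] = c_opt[bad] + rng.normal(0.0, params.sigma_s, int(bad.sum()))
    circle[is_conf] = c

    return pd.DataFrame({
        "session": session, "triplet": triplet, "triplet_position": position,
        "sector": sectors,
        "target_x": targets[:, 0], "target_y": targets[:, 1],
        "endpoint_x": endpoints[:, 0], "endpoint_y": endpoints[:, 1],
        "kind": np.where(is_conf, "confidence", "feedback"),
        "circle_radius": circle,
        "sensed_x": sensed[:, 0], "sensed_y": sensed[:, 1],
    })


def write_control_csv(df: pd.DataFrame, path, keep_sensed: bool = True) -> None:
    cols = CONTROL_COLUMNS if keep_sensed else CONTROL_COLUMNS[:-2]
    df.to_csv(path, index=False, columns=cols, float_format="%.9f")


def write_main_csv(df: pd.DataFrame, path, keep_sensed: bool = True) -> None:
    cols = MAIN_COLUMNS if keep_sensed else MAIN_COLUMNS[:-2]
    df.to_csv(path, index=False, columns=cols, float_format="%.9f")
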