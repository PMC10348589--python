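"""Bayesian observer models of sensorimotor confidence.

Three observers differ in which cues enter the posterior belief about the
reach endpoint ``e`` given a target ``t`` and a proprioceptively sensed
location ``p``:

* **ideal** — combines the motor prior ``e ~ N(t, sigma_m^2 I)`` with the
  proprioceptive likelihood ``p ~ N(e, sigma_p^2 I)``; the posterior mean is
  the reliability-weighted average (MAP estimate) of ``t`` and ``p``.
* **retrospective** — flat prior on ``e``: the belief sits on the sensed
  location with SD ``sigma_p``.
* **prospective** — ignores ``p`` entirely: the belief is the motor prior
  ``N(t, sigma_m^2 I)``, identical on every trial.

Each observer reports confidence by the circle radius that maximizes expected
gain: reward(radius) times the posterior probability that the circle captures
the endpoint dot.  Because the beliefs are isotropic Gaussians, the distance
of the endpoint from the target follows a Rice distribution and the capture
probability is its CDF.

Two conventions are supported for the ideal posterior width: ``"weighted"`` uses
variance ``(r_p/(r_p+r_m))^2 sigma_p^2`` and ``"bayes"`` uses the standard
product-of-Gaussians variance ``1/(r_m + r_p)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .task import (DEFAULT_GEOMETRY, DEFAULT_REWARD, RewardSpec, TaskGeometry,
                   as_point, reward)

__all__ = [
    "ModelKind",
    "ObserverParams",
    "Belief",
    "SearchConfig",
    "DEFAULT_SEARCH",
    "map_estimate",
    "posterior_sd",
    "endpoint_posterior",
    "radial_belief",
    "capture_probability",
    "expected_gain",
    "optimal_circle",
    "optimal_circle_radial",
]

#: beliefs narrower than this are clamped so that CDFs stay defined
MIN_BELIEF_SD = 1e-9


class ModelKind(str, Enum):
    IDEAL = "ideal"
    RETROSPECTIVE = "retrospective"
    PROSPECTIVE = "prospective"

    @classmethod
    def parse(cls, name: str) -> "ModelKind":
        aliases = {"retro": cls.RETROSPECTIVE, "prosp": cls.PROSPECTIVE,
                   "prospective": cls.PROSPECTIVE, "ideal": cls.IDEAL,
                   "retrospective": cls.RETROSPECTIVE}
        try:
            return aliases[str(name).lower()]
        except KeyError:
            raise ValueError(f"unknown model kind: {name!r}") from None


@dataclass(frozen=True)
class ObserverParams:
    """The three noise magnitudes defining an observer (all in mm).

    sigma_m: SD of isotropic motor scatter of endpoints around the target.
    sigma_p: SD of the isotropic proprioceptive measurement of the endpoint.
    sigma_s: SD of the Gaussian perturbation on the set circle radius.
    """

    sigma_m: float
    sigma_p: float
    sigma_s: float

    def __post_init__(self):
        for name in ("sigma_m", "sigma_p", "sigma_s"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def r_m(self) -> float:
        """Motor reliability 1/sigma_m^2."""
        return 1.0 / self.sigma_m**2

    @property
    def r_p(self) -> float:
        """Proprioceptive reliability 1/sigma_p^2."""
        return 1.0 / self.sigma_p**2

    @property
    def w_p(self) -> float:
        """Weight of the sensed location in the MAP estimate."""
        return self.r_p / (self.r_p + self.r_m)


@dataclass(frozen=True)
class Belief:
    """Isotropic 2-D Gaussian belief over the endpoint location."""

    mean: tuple
    sd: float

    def __post_init__(self):
        object.__setattr__(self, "mean", tuple(as_point(self.mean)))
        if not (np.isfinite(self.sd) and self.sd > 0):
            raise ValueError(f"belief sd must be finite and > 0, got {self.sd}")

    @property
    def mean_point(self) -> np.ndarray:
        return np.asarray(self.mean, float)


def map_estimate(t, p, params: ObserverParams) -> np.ndarray:
    """Reliability-weighted MAP estimate of the endpoint from target ``t``
    (prior mean) and sensed location ``p``."""
    t = as_point(t)
    p = as_point(p)
    w = params.w_p
    return w * p + (1.0 - w) * t


def posterior_sd(params: ObserverParams, convention: str = "weighted") -> float:
    """Width of the ideal observer's endpoint posterior.

    ``"weighted"``: sd = (r_p/(r_p+r_m)) * sigma_p.
    ``"bayes"``: sd = 1/sqrt(r_m + r_p).
    """
    if convention == "weighted":
        return params.w_p * params.sigma_p
    if convention == "bayes":
        return 1.0 / np.sqrt(params.r_m + params.r_p)
    raise ValueError(f"unknown posterior convention: {convention!r}")


def endpoint_posterior(model: ModelKind, t, p, params: ObserverParams,
                       convention: str = "weighted") -> Belief:
    """Posterior belief over the endpoint under each observer model.

    ``p`` may be ``None`` only for the prospective model (which ignores it).
    """
    model = ModelKind(model)
    t = as_point(t)
    if model is ModelKind.PROSPECTIVE:
        return Belief(tuple(t), params.sigma_m)
    if p is None:
        raise ValueError(f"{model.value} model requires a sensed location")
    p = as_point(p)
    if model is ModelKind.RETROSPECTIVE:
        return Belief(tuple(p), params.sigma_p)
    mean = map_estimate(t, p, params)
    return Belief(tuple(mean), posterior_sd(params, convention))


def radial_belief(model: ModelKind, sensed_distance, params: ObserverParams,
                  convention: str = "weighted"):
    """Belief reduced to the target frame: (offset of belief mean from the
    target, belief SD).  Vectorized over ``sensed_distance``.

    Valid because all beliefs are isotropic and their means lie on the
    target-to-sensed-location ray, so the optimal circle depends on the
    sensed location only through its distance from the target.
    """
    model = ModelKind(model)
    d = np.asarray(sensed_distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("sensed_distance must be non-negative")
    if model is ModelKind.PROSPECTIVE:
        return np.zeros_like(d), params.sigma_m
    if model is ModelKind.RETROSPECTIVE:
        return d, params.sigma_p
    return params.w_p * d, posterior_sd(params, convention)


def _distance_cdf(r_total, nu, sd):
    """CDF at ``r_total`` of the distance from the target of an isotropic
    2-D Gaussian with mean offset ``nu`` and per-axis SD ``sd`` (Rice)."""
    sd = max(float(sd), MIN_BELIEF_SD)
    return stats.rice.cdf(np.asarray(r_total, float), b=np.asarray(nu, float) / sd,
                          scale=sd)


def capture_probability(belief: Belief, t, circle_radius,
                        geometry: TaskGeometry = DEFAULT_GEOMETRY):
    """Posterior probability that a circle of ``circle_radius`` around ``t``
    captures the endpoint dot.  Vectorized over ``circle_radius``."""
    r = np.asarray(circle_radius, dtype=float)
    if np.any(r < 0):
        raise ValueError("circle_radius must be non-negative")
    nu = float(np.linalg.norm(belief.mean_point - as_point(t)))
    out = _distance_cdf(r + geometry.endpoint_dot_radius, nu, belief.sd)
    return out if out.ndim else float(out)


def expected_gain(circle_radius, belief: Belief, t,
                  reward_spec: RewardSpec = DEFAULT_REWARD,
                  geometry: TaskGeometry = DEFAULT_GEOMETRY):
    """Expected points for a circle: reward(radius) x capture probability."""
    return reward(circle_radius, reward_spec) * capture_probability(
        belief, t, circle_radius, geometry)


@dataclass(frozen=True)
class SearchConfig:
    """Grid search for the expected-gain-maximizing circle radius.

    The grid spans [0, max_radius] at ``step`` resolution; ties are broken to
    the smallest radius.  ``max_radius`` > the reward's zero radius so the
    optimum is always bracketed.
    """

    max_radius: float = 80.0
    step: float = 0.1

    def __post_init__(self):
        if self.max_radius <= 0 or self.step <= 0:
            raise ValueError("max_radius and step must be positive")

    @property
    def radii(self) -> np.ndarray:
        n = int(round(self.max_radius / self.step)) + 1
        return np.arange(n) * self.step


DEFAULT_SEARCH = SearchConfig()


def _eg_matrix(nu, sd, radii, reward_spec, geometry):
    cdf = _distance_cdf(radii[None, :] + geometry.endpoint_dot_radius,
                        np.asarray(nu, float)[:, None], sd)
    return reward(radii, reward_spec)[None, :] * cdf


def optimal_circle_radial(nu, sd, reward_spec: RewardSpec = DEFAULT_REWARD,
                          geometry: TaskGeometry = DEFAULT_GEOMETRY,
                          search: SearchConfig = DEFAULT_SEARCH,
                          refine: bool = False) -> np.ndarray:
    """Expected-gain-maximizing circle radius for beliefs given in radial form.

    Vectorized over ``nu`` (belief-mean offsets from the target; ``sd`` is a
    shared scalar).  With ``refine=True`` a two-stage scan is used (coarse
    pass at 10x the step, then the full-resolution grid within one coarse
    cell of the coarse argmax); expected gain is unimodal along the radius for
    these beliefs, so this reproduces the brute-force grid argmax at a
    fraction of the cost.
    """
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    radii = search.radii
    if not refine or len(radii) < 50:
        eg = _eg_matrix(nu, sd, radii, reward_spec, geometry)
        best = np.argmax(eg, axis=1)
        if np.any(np.max(eg, axis=1) <= 0.0):
            warnings.warn("expected gain vanished over the whole search grid; "
                          "returning the smallest radius", RuntimeWarning)
        return radii[best]

    coarse_step = 10
    coarse = radii[::coarse_step]
    eg_c = _eg_matrix(nu, sd, coarse, reward_spec, geometry)
    ic = np.argmax(eg_c, axis=1)
    if np.any(np.max(eg_c, axis=1) <= 0.0):
        warnings.warn("expected gain vanished over the whole search grid; "
                      "returning the smallest radius", RuntimeWarning)
    # full-resolution pass within +/- one coarse cell of the coarse argmax
    lo = np.maximum(ic - 1, 0) * coarse_step
    offsets = np.arange(2 * coarse_step + 1)
    idx = np.minimum(lo[:, None] + offsets[None, :], len(radii) - 1)
    fine = radii[idx]
    cdf = _distance_cdf(fine + geometry.endpoint_dot_radius, nu[:, None], sd)
    eg_f = reward(fine.ravel(), reward_spec).reshape(fine.shape) * cdf
    best = idx[np.arange(len(nu)), np.argmax(eg_f, axis=1)]
    return radii[best]


def optimal_circle(model: ModelKind, params: ObserverParams, sensed_distance,
                   reward_spec: RewardSpec = DEFAULT_REWARD,
                   geometry: TaskGeometry = DEFAULT_GEOMETRY,
                   search: SearchConfig = DEFAULT_SEARCH,
                   convention: str = "weighted"):
    """Optimal circle radius for a sensed endpoint at ``sensed_distance`` from
    the target.  Constant in ``sensed_distance`` for the prospective model.
    Vectorized over ``sensed_distance``."""
    nu, sd = radial_belief(model, sensed_distance, params, convention)
    out = optimal_circle_radial(np.atleast_1d(nu), sd, reward_spec, geometry,
                                search)
    return out if np.ndim(sensed_distance) else float(out[0])
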