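"""Likelihoods and maximum-likelihood fitting of the observer models.

The joint log-likelihood of a parameter set Theta = (sigma_m, sigma_p,
sigma_s) over both tasks is the sum of

1. the Gaussian density of each control-task endpoint around the target,
2. the Gaussian density of each control-task indicated endpoint around its
   MAP prediction (exact sampling SD: (r_p/(r_p+r_m)) * sigma_p),
3. the Gaussian density of every main-task endpoint around its target, and
4. the likelihood of each set circle radius.

Term 4 is the crux: the experimenter never observes the sensed location, so
for the ideal and retrospective models the circle likelihood marginalizes
over it.  Two discretizations are provided: a 2-D grid of sensed locations
around the true endpoint (the direct transcription of the integral), and an
equivalent 1-D quadrature over the sensed distance from the target, which is
sufficient because the optimal circle depends on the sensed location only
through that distance (its density is Rice).  The prospective model needs no
marginalization: its intended circle is constant.

The circle-setting density is an *untruncated* normal around the policy
optimum even though physical radii are non-negative; the truncation applied
when simulating is deliberately ignored here, matching the model definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .observers import (DEFAULT_SEARCH, ModelKind, ObserverParams,
                        SearchConfig, optimal_circle_radial, radial_belief)
from .task import DEFAULT_GEOMETRY, DEFAULT_REWARD, RewardSpec, TaskGeometry

__all__ = [
    "IntegrationConfig",
    "FitConfig",
    "FitResult",
    "PolicyTable",
    "policy_table",
    "control_loglik",
    "confidence_loglik",
    "total_loglik",
    "moment_start",
    "fit_model",
]

_LOG_FLOOR = np.log(1e-300)
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class IntegrationConfig:
    """Discretization of the sensed-location marginal.

    mode: "1d-radial" (Gauss-Legendre over the sensed distance) or "2d-grid"
    (Riemann sum over a square grid of sensed locations).
    grid_half_width: half-width of either discretization in multiples of
    sigma_p.  grid_points_per_axis: nodes per axis of the 2-D grid.
    radial_nodes: Gauss-Legendre nodes of the 1-D rule.  policy_table_step /
    policy_table_max: resolution and range (mm) of the memoized policy table.
    """

    mode: str = "1d-radial"
    grid_half_width: float = 4.0
    grid_points_per_axis: int = 41
    radial_nodes: int = 200
    policy_table_step: float = 0.5
    policy_table_max: float = 300.0

    def __post_init__(self):
        if self.mode not in ("1d-radial", "2d-grid"):
            raise ValueError(f"unknown integration mode: {self.mode!r}")
        if self.grid_half_width < 2:
            raise ValueError("grid_half_width must be >= 2")
        if min(self.grid_points_per_axis, self.radial_nodes) < 3:
            raise ValueError("node counts must be >= 3")
        if self.policy_table_step <= 0 or self.policy_table_max <= 0:
            raise ValueError("policy table step and max must be positive")


DEFAULT_INTEGRATION = IntegrationConfig()


@dataclass(frozen=True)
class FitConfig:
    """Multi-start Nelder-Mead settings for the maximum-likelihood fit.

    Optimization runs on log-parameters within [lower, upper] mm.  The first
    start uses moment-based estimates; the rest perturb them by log-normal
    factors (SD ``start_jitter`` in log space), reproducibly under ``seed``.
    """

    n_starts: int = 5
    lower: float = 0.5
    upper: float = 200.0
    tol: float = 1e-3
    xtol: float = 1e-3
    maxfev: int = 600
    start_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lower < self.upper):
            raise ValueError("require 0 < lower < upper")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    model: ModelKind
    params: ObserverParams
    loglik: float
    n_control: int
    n_main: int
    n_confidence: int
    converged: bool

    @property
    def n_obs(self) -> int:
        """Likelihood-contributing observations: control trials + main-task
        endpoints + confidence settings (the BIC sample size)."""
        return self.n_control + self.n_main + self.n_confidence

    def to_dict(self) -> dict:
        return {
            "model": self.model.value,
            "sigma_m": self.params.sigma_m,
            "sigma_p": self.params.sigma_p,
            "sigma_s": self.params.sigma_s,
            "loglik": self.loglik,
            "n_control": self.n_control,
            "n_main": self.n_main,
            "n_confidence": self.n_confidence,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


class PolicyTable:
    """Optimal circle radius tabulated over sensed distance, with linear
    interpolation between nodes (constant for the prospective model)."""

    def __init__(self, model: ModelKind, distances: np.ndarray,
                 values: np.ndarray):
        self.model = ModelKind(model)
        self.distances = np.asarray(distances, float)
        self.values = np.asarray(values, float)

    def __call__(self, d):
        if self.model is ModelKind.PROSPECTIVE:
            out = np.full_like(np.asarray(d, float), self.values[0])
            return out if out.ndim else float(out)
        return np.interp(d, self.distances, self.values)


def policy_table(model: ModelKind, params: ObserverParams,
                 cfg: IntegrationConfig = DEFAULT_INTEGRATION,
                 reward_spec: RewardSpec = DEFAULT_REWARD,
                 geometry: TaskGeometry = DEFAULT_GEOMETRY,
                 search: SearchConfig = DEFAULT_SEARCH,
                 convention: str = "weighted") -> PolicyTable:
    """Tabulate the expected-gain-optimal circle over sensed distance."""
    model = ModelKind(model)
    if model is ModelKind.PROSPECTIVE:
        nu, sd = radial_belief(model, 0.0, params, convention)
        val = optimal_circle_radial(np.atleast_1d(nu), sd, reward_spec,
                                    geometry, search, refine=True)
        return PolicyTable(model, np.array([0.0]), val)
    n = int(round(cfg.policy_table_max / cfg.policy_table_step)) + 1
    distances = np.arange(n) * cfg.policy_table_step
    nu, sd = radial_belief(model, distances, params, convention)
    values = optimal_circle_radial(nu, sd, reward_spec, geometry, search,
                                   refine=True)
    return PolicyTable(model, distances, values)


def _iso2_logpdf(x, mu, sigma):
    """Log density of an isotropic bivariate normal, summed over rows."""
    r2 = np.sum((np.asarray(x, float) - np.asarray(mu, float))**2, axis=-1)
    n = r2.shape[0] if r2.ndim else 1
    return float(-n * (_LOG_2PI + 2.0 * np.log(sigma)) - np.sum(r2) /
                 (2.0 * sigma**2))


def _xy(df: pd.DataFrame, stem: str) -> np.ndarray:
    return df[[f"{stem}_x", f"{stem}_y"]].to_numpy(float)


def control_loglik(control: pd.DataFrame, sigma_m: float,
                   sigma_p: float) -> float:
    """Log-likelihood of the control task: endpoint scatter around the target
    plus indicated-endpoint scatter around the MAP prediction."""
    if len(control) == 0:
        raise ValueError("control data is empty")
    if sigma_m <= 0 or sigma_p <= 0:
        raise ValueError("sigmas must be positive")
    t = _xy(control, "target")
    e = _xy(control, "endpoint")
    i = _xy(control, "indicated")
    w = sigma_m**2 / (sigma_m**2 + sigma_p**2)  # = r_p / (r_p + r_m)
    ll = _iso2_logpdf(e, t, sigma_m)
    ll += _iso2_logpdf(i, w * e + (1.0 - w) * t, w * sigma_p)
    return ll


@lru_cache(maxsize=8)
def _leggauss(n: int):
    return np.polynomial.legendre.leggauss(n)


def _confidence_rows(main: pd.DataFrame) -> pd.DataFrame:
    conf = main[main["kind"] == "confidence"]
    if conf["circle_radius"].isna().any():
        raise ValueError("confidence rows must all carry a circle_radius")
    return conf


def _marginal_radial(nu_e, c_obs, params, table, cfg):
    """Per-trial circle-setting likelihood, marginalized over the sensed
    distance d ~ Rice(offset ||e - t||, scale sigma_p)."""
    x, w = _leggauss(cfg.radial_nodes)
    half = cfg.grid_half_width * params.sigma_p
    lo = np.maximum(0.0, nu_e - half)
    hi = nu_e + half
    mid, rad = (hi + lo) / 2.0, (hi - lo) / 2.0
    d = mid[:, None] + rad[:, None] * x[None, :]
    wts = w[None, :] * rad[:, None] * stats.rice.pdf(
        d, b=nu_e[:, None] / params.sigma_p, scale=params.sigma_p)
    wts /= np.sum(wts, axis=1, keepdims=True)
    dens = np.exp(-0.5 * ((c_obs[:, None] - table(d)) / params.sigma_s)**2) / (
        np.sqrt(2.0 * np.pi) * params.sigma_s)
    return np.sum(wts * dens, axis=1)


def _marginal_grid(e, t, c_obs, params, table, cfg):
    """Per-trial circle-setting likelihood via the 2-D sensed-location grid
    centered on each true endpoint (renormalized Riemann sum)."""
    g = cfg.grid_points_per_axis
    off = np.linspace(-cfg.grid_half_width * params.sigma_p,
                      cfg.grid_half_width * params.sigma_p, g)
    w1 = np.exp(-0.5 * (off / params.sigma_p)**2)
    w2 = np.outer(w1, w1)
    w2 /= w2.sum()
    out = np.empty(len(c_obs))
    norm = np.sqrt(2.0 * np.pi) * params.sigma_s
    for j in range(len(c_obs)):
        px = e[j, 0] + off
        py = e[j, 1] + off
        d = np.hypot(px[:, None] - t[j, 0], py[None, :] - t[j, 1])
        dens = np.exp(-0.5 * ((c_obs[j] - table(d)) / params.sigma_s)**2) / norm
        out[j] = np.sum(w2 * dens)
    return out


def confidence_loglik(model: ModelKind, conf: pd.DataFrame,
                      params: ObserverParams,
                      cfg: IntegrationConfig = DEFAULT_INTEGRATION,
                      reward_spec: RewardSpec = DEFAULT_REWARD,
                      geometry: TaskGeometry = DEFAULT_GEOMETRY,
                      search: SearchConfig = DEFAULT_SEARCH,
                      convention: str = "weighted",
                      table: PolicyTable | None = None,
                      return_per_trial: bool = False):
    """Summed log-likelihood of the observed circle radii (confidence rows).

    Underflowing per-trial marginals are floored at 1e-300.
    """
    model = ModelKind(model)
    if conf["circle_radius"].isna().any():
        raise ValueError("confidence rows must all carry a circle_radius")
    c_obs = conf["circle_radius"].to_numpy(float)
    if table is None:
        table = policy_table(model, params, cfg, reward_spec, geometry,
                             search, convention)
    if model is ModelKind.PROSPECTIVE:
        c_opt = table(0.0)
        per = stats.norm.pdf(c_obs, loc=c_opt, scale=params.sigma_s)
    else:
        t = _xy(conf, "target")
        e = _xy(conf, "endpoint")
        if cfg.mode == "1d-radial":
            nu_e = np.linalg.norm(e - t, axis=1)
            per = _marginal_radial(nu_e, c_obs, params, table, cfg)
        else:
            per = _marginal_grid(e, t, c_obs, params, table, cfg)
    logs = np.log(np.maximum(per, 1e-300))
    if return_per_trial:
        return logs
    return float(np.sum(logs))


def total_loglik(model: ModelKind, control: pd.DataFrame, main: pd.DataFrame,
                 params: ObserverParams,
                 cfg: IntegrationConfig = DEFAULT_INTEGRATION,
                 reward_spec: RewardSpec = DEFAULT_REWARD,
                 geometry: TaskGeometry = DEFAULT_GEOMETRY,
                 search: SearchConfig = DEFAULT_SEARCH,
                 convention: str = "weighted") -> float:
    """Joint log-likelihood over the control task and the main task.

    All main-task endpoints (feedback and confidence trials alike) contribute
    the Gaussian endpoint term; only confidence rows contribute the
    circle-setting term.
    """
    if len(control) == 0 or len(main) == 0:
        raise ValueError("both datasets must be non-empty")
    ll = control_loglik(control, params.sigma_m, params.sigma_p)
    ll += _iso2_logpdf(_xy(main, "endpoint"), _xy(main, "target"),
                       params.sigma_m)
    conf = _confidence_rows(main)
    ll += confidence_loglik(model, conf, params, cfg, reward_spec, geometry,
                            search, convention)
    return ll


def moment_start(control: pd.DataFrame, main: pd.DataFrame,
                 lower: float = 0.5, upper: float = 200.0) -> ObserverParams:
    """Method-of-moments initialization for the optimizer.

    sigma_m from pooled endpoint scatter; sigma_p by inverting the MAP weight
    estimated from the regression of indicated on true endpoints in the
    control task; sigma_s from the circle-radius SD (an overestimate for
    adaptive policies, which is a harmless place to start).
    """
    res_c = _xy(control, "endpoint") - _xy(control, "target")
    res_m = _xy(main, "endpoint") - _xy(main, "target")
    res = np.concatenate([res_c, res_m])
    sigma_m = float(np.sqrt(np.mean(res**2)))

    ic = _xy(control, "indicated") - _xy(control, "target")
    ec = res_c
    w = float(np.sum(ic * ec) / np.sum(ec**2))
    w = np.clip(w, 0.05, 0.95)
    sigma_p = sigma_m * np.sqrt((1.0 - w) / w)

    c = _confidence_rows(main)["circle_radius"].to_numpy(float)
    sigma_s = float(np.std(c)) if len(c) > 1 else 5.0

    clip = lambda v: float(np.clip(v, lower * 1.01, upper * 0.99))
    return ObserverParams(clip(sigma_m), clip(sigma_p), clip(sigma_s))


def fit_model(model: ModelKind, control: pd.DataFrame, main: pd.DataFrame,
              fit_cfg: FitConfig = FitConfig(),
              integration_cfg: IntegrationConfig = DEFAULT_INTEGRATION,
              reward_spec: RewardSpec = DEFAULT_REWARD,
              geometry: TaskGeometry = DEFAULT_GEOMETRY,
              search: SearchConfig = DEFAULT_SEARCH,
              convention: str = "weighted") -> FitResult:
    """Maximum-likelihood fit of one observer model to both tasks.

    Derivative-free (Nelder-Mead) optimization on log-parameters from
    ``n_starts`` initializations; returns the best run.
    """
    model = ModelKind(model)
    conf = _confidence_rows(main)

    # sufficient statistics for the three Gaussian terms (exact, cheap)
    tc, ec, ic = (_xy(control, s) for s in ("target", "endpoint", "indicated"))
    n_c = len(control)
    C = float(np.sum((ec - tc)**2))
    di, de = ic - tc, ec - tc
    A, B = float(np.sum(di**2)), float(np.sum(di * de))
    em, tm = _xy(main, "endpoint"), _xy(main, "target")
    n_m = len(main)
    D = float(np.sum((em - tm)**2))
    nu_e = np.linalg.norm(_xy(conf, "endpoint") - _xy(conf, "target"), axis=1)
    c_obs = conf["circle_radius"].to_numpy(float)

    def loglik(params: ObserverParams) -> float:
        sm, sp, ss = params.sigma_m, params.sigma_p, params.sigma_s
        w = sm**2 / (sm**2 + sp**2)
        ll = -n_c * (_LOG_2PI + 2 * np.log(sm)) - C / (2 * sm**2)
        ssw = A - 2 * w * B + w**2 * C
        ll += -n_c * (_LOG_2PI + 2 * np.log(w * sp)) - ssw / (2 * (w * sp)**2)
        ll += -n_m * (_LOG_2PI + 2 * np.log(sm)) - D / (2 * sm**2)
        table = policy_table(model, params, integration_cfg, reward_spec,
                             geometry, search, convention)
        if model is ModelKind.PROSPECTIVE:
            per = stats.norm.pdf(c_obs, loc=table(0.0), scale=ss)
        elif integration_cfg.mode == "1d-radial":
            per = _marginal_radial(nu_e, c_obs, params, table,
                                   integration_cfg)
        else:
            per = _marginal_grid(_xy(conf, "endpoint"), _xy(conf, "target"),
                                 c_obs, params, table, integration_cfg)
        return ll + float(np.sum(np.log(np.maximum(per, 1e-300))))

    def objective(logtheta: np.ndarray) -> float:
        return -loglik(ObserverParams(*np.exp(logtheta)))

    start = moment_start(control, main, fit_cfg.lower, fit_cfg.upper)
    x0 = np.log([start.sigma_m, start.sigma_p, start.sigma_s])
    rng = np.random.default_rng(fit_cfg.seed)
    bounds = [(np.log(fit_cfg.lower), np.log(fit_cfg.upper))] * 3
    starts = [x0] + [
        np.clip(x0 + rng.normal(0.0, fit_cfg.start_jitter, 3),
                bounds[0][0], bounds[0][1])
        for _ in range(fit_cfg.n_starts - 1)
    ]

    best = None
    for s in starts:
        res = optimize.minimize(
            objective, s, method="Nelder-Mead", bounds=bounds,
            options={"xatol": fit_cfg.xtol, "fatol": fit_cfg.tol,
                     "maxfev": fit_cfg.maxfev})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimization starts failed")
    params = ObserverParams(*np.exp(best.x))
    return FitResult(model=model, params=params, loglik=-float(best.fun),
                     n_control=n_c, n_main=n_m, n_confidence=len(conf),
                     converged=bool(best.success))
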