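"""Model comparison, recovery studies, efficiency simulation, behavioral
summaries, and posterior-predictive checks.

Because all three observer models are fit jointly to both tasks they share
the same three parameters, so BIC selection reduces to log-likelihood
comparison; BIC scores are still reported with n = the number of
likelihood-contributing observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import (DEFAULT_INTEGRATION, FitConfig, FitResult,
                      IntegrationConfig, fit_model, policy_table)
from .observers import (DEFAULT_SEARCH, ModelKind, ObserverParams,
                        SearchConfig)
from .simulate import (ParamPrior, sample_parameters, simulate_control_task,
                       simulate_main_task)
from .task import (DEFAULT_GEOMETRY, DEFAULT_REWARD, RewardSpec, TaskGeometry,
                   capture, max_points_for_endpoint, reward)

__all__ = [
    "MODEL_ORDER",
    "ComparisonTable",
    "ConfusionMatrix",
    "BehavioralSummary",
    "PosteriorPredictive",
    "bic",
    "compare_models",
    "model_recovery",
    "parameter_recovery",
    "efficiency",
    "behavioral_summary",
    "rotate_to_target_frame",
    "posterior_predictive",
]

MODEL_ORDER = (ModelKind.IDEAL, ModelKind.RETROSPECTIVE, ModelKind.PROSPECTIVE)


def bic(loglik: float, n: int, k: int) -> float:
    """Bayesian Information Criterion k*ln(n) - 2*loglik (lower is better)."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    return k * np.log(n) - 2.0 * loglik


@dataclass(frozen=True)
class ComparisonTable:
    """Per-model BIC comparison on one dataset; the winner has delta = 0."""

    models: tuple
    logliks: tuple
    bics: tuple
    delta_bic: tuple
    winner: ModelKind

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": [m.value for m in self.models],
            "loglik": self.logliks,
            "bic": self.bics,
            "delta_bic": self.delta_bic,
        })


def compare_models(fits: list[FitResult], n: int | None = None,
                   k: int = 3) -> ComparisonTable:
    """Build the BIC comparison from fits of the three models to one dataset."""
    counts = {(f.n_control, f.n_main, f.n_confidence) for f in fits}
    if len(counts) != 1:
        raise ValueError("fits were not computed on identical data")
    if n is None:
        n = fits[0].n_obs
    bics = np.array([bic(f.loglik, n, k) for f in fits])
    delta = bics - bics.min()
    winner = fits[int(np.argmin(bics))].model
    return ComparisonTable(models=tuple(f.model for f in fits),
                           logliks=tuple(float(f.loglik) for f in fits),
                           bics=tuple(float(b) for b in bics),
                           delta_bic=tuple(float(d) for d in delta),
                           winner=winner)


@dataclass
class ConfusionMatrix:
    """Model-recovery counts: rows = generating model, cols = selected."""

    counts: np.ndarray
    models: tuple = MODEL_ORDER

    @property
    def recovery_rate(self) -> float:
        return float(np.trace(self.counts) / np.sum(self.counts))

    def to_frame(self) -> pd.DataFrame:
        names = [m.value for m in self.models]
        return pd.DataFrame(self.counts, index=names, columns=names)


def _simulate_dataset(model, params, n_control, n_triplets, geometry,
                      reward_spec, search, convention, rng):
    control = simulate_control_task(params, n_control, geometry, rng)
    main = simulate_main_task(model, params, n_triplets, geometry,
                              reward_spec, rng, search=search,
                              convention=convention)
    return control, main


def model_recovery(n_sets: int = 20, prior: ParamPrior | None = None,
                   n_control: int = 300, n_triplets: int = 300,
                   fit_cfg: FitConfig = FitConfig(),
                   integration_cfg: IntegrationConfig = DEFAULT_INTEGRATION,
                   seed=None,
                   reward_spec: RewardSpec = DEFAULT_REWARD,
                   geometry: TaskGeometry = DEFAULT_GEOMETRY,
                   search: SearchConfig = DEFAULT_SEARCH,
                   convention: str = "weighted",
                   return_records: bool = False):
    """Simulate datasets from every model under prior-sampled parameters,
    refit all three models to each, and count BIC selections."""
    rng = np.random.default_rng(seed)
    param_sets = sample_parameters(n_sets, prior, rng)
    idx = {m: j for j, m in enumerate(MODEL_ORDER)}
    counts = np.zeros((3, 3), dtype=int)
    records = []
    for params in param_sets:
        for gen in MODEL_ORDER:
            control, main = _simulate_dataset(
                gen, params, n_control, n_triplets, geometry, reward_spec,
                search, convention, rng)
            fits = [fit_model(m, control, main, fit_cfg, integration_cfg,
                              reward_spec, geometry, search, convention)
                    for m in MODEL_ORDER]
            table = compare_models(fits)
            counts[idx[gen], idx[table.winner]] += 1
            records.append({"generating": gen.value,
                            "selected": table.winner.value,
                            "sigma_m": params.sigma_m,
                            "sigma_p": params.sigma_p,
                            "sigma_s": params.sigma_s,
                            "delta_bic": table.delta_bic})
    cm = ConfusionMatrix(counts=counts)
    return (cm, records) if return_records else cm


def parameter_recovery(n_sets: int = 20, prior: ParamPrior | None = None,
                       n_control: int = 300, n_triplets: int = 300,
                       fit_cfg: FitConfig = FitConfig(),
                       integration_cfg: IntegrationConfig = DEFAULT_INTEGRATION,
                       seed=None,
                       models=MODEL_ORDER,
                       reward_spec: RewardSpec = DEFAULT_REWARD,
                       geometry: TaskGeometry = DEFAULT_GEOMETRY,
                       search: SearchConfig = DEFAULT_SEARCH,
                       convention: str = "weighted") -> pd.DataFrame:
    """Self-fit recovery: for each model, simulate with prior-sampled
    parameters, fit the same model, and summarize percentage errors.

    Returns a table with mean/SD of the signed error and of the absolute
    error, both as percent of ground truth, per (model, parameter).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for model in models:
        model = ModelKind(model)
        errors = {"sigma_m": [], "sigma_p": [], "sigma_s": []}
        for params in sample_parameters(n_sets, prior, rng):
            control, main = _simulate_dataset(
                model, params, n_control, n_triplets, geometry, reward_spec,
                search, convention, rng)
            fit = fit_model(model, control, main, fit_cfg, integration_cfg,
                            reward_spec, geometry, search, convention)
            for name in errors:
                truth = getattr(params, name)
                est = getattr(fit.params, name)
                errors[name].append(100.0 * (est - truth) / truth)
        for name, errs in errors.items():
            errs = np.asarray(errs)
            rows.append({
                "model": model.value, "parameter": name,
                "mean_signed_pct": float(np.mean(errs)),
                "sd_signed_pct": float(np.std(errs, ddof=1)) if len(errs) > 1
                else 0.0,
                "mean_abs_pct": float(np.mean(np.abs(errs))),
                "sd_abs_pct": float(np.std(np.abs(errs), ddof=1))
                if len(errs) > 1 else 0.0,
                "n": len(errs),
            })
    return pd.DataFrame(rows)


def efficiency(observers, n_trials: int = 100_000,
               reward_spec: RewardSpec = DEFAULT_REWARD,
               geometry: TaskGeometry = DEFAULT_GEOMETRY,
               search: SearchConfig = DEFAULT_SEARCH,
               convention: str = "weighted", seed=None) -> pd.DataFrame:
    """Mean points per confidence trial for each (label, params, policy).

    ``observers`` is a list of (label, ObserverParams, policy) where policy
    is a ModelKind or "oracle" (the smallest capturing circle, set without
    setting noise: an upper-bound reference with perfect knowledge of the
    endpoint — under setting noise its boundary circle would miss half the
    time, which is not the intended bound).  Endpoints, sensed locations and
    setting noise are drawn fresh per observer; points use the task's reward
    and capture rule.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, params, policy in observers:
        e = rng.normal(0.0, params.sigma_m, (n_trials, 2))
        err = np.linalg.norm(e, axis=1)
        oracle = policy == "oracle"
        if oracle:
            intended = np.maximum(err - geometry.endpoint_dot_radius, 0.0)
        else:
            policy = ModelKind(policy)
            p = e + rng.normal(0.0, params.sigma_p, (n_trials, 2))
            d = np.linalg.norm(p, axis=1)
            table = policy_table(
                policy, params,
                IntegrationConfig(policy_table_step=0.5,
                                  policy_table_max=float(np.max(d)) + 1.0),
                reward_spec, geometry, search, convention)
            intended = table(d)
        if oracle:
            c = intended
        else:
            c = intended + rng.normal(0.0, params.sigma_s, n_trials)
            while np.any(c < 0):
                bad = c < 0
                c[bad] = intended[bad] + rng.normal(0.0, params.sigma_s,
                                                    int(bad.sum()))
        won = capture(err, c, geometry)
        pts = np.where(won, reward(c, reward_spec), 0.0)
        rows.append({
            "label": label,
            "policy": policy if isinstance(policy, str) else policy.value,
            "sigma_m": params.sigma_m, "sigma_p": params.sigma_p,
            "sigma_s": params.sigma_s,
            "points_per_trial": float(np.mean(pts)),
            "se_points": float(np.std(pts, ddof=1) / np.sqrt(n_trials)),
            "capture_fraction": float(np.mean(won)),
            "mean_circle": float(np.mean(c)),
            "n_trials": n_trials,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BehavioralSummary:
    mean_reach_error: float
    mean_circle: float
    capture_fraction: float
    total_points: float
    fraction_of_max_points: float
    pearson_r: float
    pearson_p: float
    degenerate_correlation: bool
    n_confidence: int


def behavioral_summary(main: pd.DataFrame,
                       reward_spec: RewardSpec = DEFAULT_REWARD,
                       geometry: TaskGeometry = DEFAULT_GEOMETRY
                       ) -> BehavioralSummary:
    """Descriptive statistics of main-task performance.

    The error-confidence Pearson correlation is taken over confidence trials;
    a constant circle vector is reported as r = 0, p = 1 with a degeneracy
    flag instead of NaN.
    """
    if len(main) == 0:
        raise ValueError("empty main-task data")
    conf = main[main["kind"] == "confidence"]
    if len(conf) == 0:
        raise ValueError("no confidence trials present")
    e = conf[["endpoint_x", "endpoint_y"]].to_numpy(float)
    t = conf[["target_x", "target_y"]].to_numpy(float)
    err = np.linalg.norm(e - t, axis=1)
    c = conf["circle_radius"].to_numpy(float)
    won = capture(err, c, geometry)
    pts = np.where(won, reward(c, reward_spec), 0.0)
    best = max_points_for_endpoint(err, reward_spec, geometry)
    degenerate = bool(np.all(c == c[0])) or len(conf) < 3
    if degenerate:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(err, c)
    all_err = np.linalg.norm(
        main[["endpoint_x", "endpoint_y"]].to_numpy(float)
        - main[["target_x", "target_y"]].to_numpy(float), axis=1)
    return BehavioralSummary(
        mean_reach_error=float(np.mean(all_err)),
        mean_circle=float(np.mean(c)),
        capture_fraction=float(np.mean(won)),
        total_points=float(np.sum(pts)),
        fraction_of_max_points=float(np.sum(pts) / np.sum(best)),
        pearson_r=float(r), pearson_p=float(p),
        degenerate_correlation=degenerate,
        n_confidence=len(conf),
    )


def rotate_to_target_frame(trials: pd.DataFrame) -> np.ndarray:
    """Endpoint offsets rotated so that +y points from start toward the
    target of each trial (for endpoint-isotropy checks).  Norm-preserving."""
    t = trials[["target_x", "target_y"]].to_numpy(float)
    e = trials[["endpoint_x", "endpoint_y"]].to_numpy(float)
    norm = np.linalg.norm(t, axis=1)
    if np.any(norm == 0):
        raise ValueError("target at the origin has no direction")
    u = t / norm[:, None]          # unit vector toward the target -> +y
    perp = np.stack([u[:, 1], -u[:, 0]], axis=1)   # right-handed +x
    off = e - t
    return np.stack([np.sum(off * perp, axis=1),
                     np.sum(off * u, axis=1)], axis=1)


@dataclass(frozen=True)
class PosteriorPredictive:
    """Re-simulated confidence reports with targets and endpoints held fixed."""

    model: ModelKind
    capture_fraction: np.ndarray
    total_points: np.ndarray
    mean_circle: np.ndarray
    ks_distance: np.ndarray
    observed_capture_fraction: float
    observed_total_points: float
    observed_mean_circle: float

    def summary(self) -> dict:
        return {
            "model": self.model.value,
            "mean_capture_fraction": float(np.mean(self.capture_fraction)),
            "mean_total_points": float(np.mean(self.total_points)),
            "mean_circle": float(np.mean(self.mean_circle)),
            "mean_ks_distance": float(np.mean(self.ks_distance)),
            "observed_capture_fraction": self.observed_capture_fraction,
            "observed_total_points": self.observed_total_points,
            "observed_mean_circle": self.observed_mean_circle,
        }


def posterior_predictive(fit: FitResult, main: pd.DataFrame,
                         n_sims: int = 200, seed=None,
                         reward_spec: RewardSpec = DEFAULT_REWARD,
                         geometry: TaskGeometry = DEFAULT_GEOMETRY,
                         search: SearchConfig = DEFAULT_SEARCH,
                         convention: str = "weighted") -> PosteriorPredictive:
    """Simulate confidence reports from a fitted model, holding each trial's
    target and endpoint fixed, and compare to the observed circle radii via
    the Kolmogorov-Smirnov statistic."""
    rng = np.random.default_rng(seed)
    conf = main[main["kind"] == "confidence"]
    e = conf[["endpoint_x", "endpoint_y"]].to_numpy(float)
    t = conf[["target_x", "target_y"]].to_numpy(float)
    c_obs = conf["circle_radius"].to_numpy(float)
    err = np.linalg.norm(e - t, axis=1)
    params = fit.params
    n = len(conf)

    model = ModelKind(fit.model)
    if model is ModelKind.PROSPECTIVE:
        intended = np.zeros((n_sims, n))
        table = policy_table(model, params, DEFAULT_INTEGRATION, reward_spec,
                             geometry, search, convention)
        intended[:] = table(0.0)
    else:
        p = e[None, :, :] + rng.normal(0.0, params.sigma_p, (n_sims, n, 2))
        d = np.linalg.norm(p - t[None, :, :], axis=2)
        table = policy_table(
            model, params,
            IntegrationConfig(policy_table_max=float(np.max(d)) + 1.0),
            reward_spec, geometry, search, convention)
        intended = table(d)
    c = intended + rng.normal(0.0, params.sigma_s, (n_sims, n))
    while np.any(c < 0):
        bad = c < 0
        c[bad] = intended[bad] + rng.normal(0.0, params.sigma_s,
                                            int(bad.sum()))
    won = capture(np.broadcast_to(err, c.shape), c, geometry)
    pts = np.where(won, reward(c, reward_spec), 0.0)
    ks = np.array([stats.ks_2samp(c_obs, c[s]).statistic
                   for s in range(n_sims)])
    obs_won = capture(err, c_obs, geometry)
    obs_pts = np.where(obs_won, reward(c_obs, reward_spec), 0.0)
    return PosteriorPredictive(
        model=model,
        capture_fraction=won.mean(axis=1),
        total_points=pts.sum(axis=1),
        mean_circle=c.mean(axis=1),
        ks_distance=ks,
        observed_capture_fraction=float(obs_won.mean()),
        observed_total_points=float(obs_pts.sum()),
        observed_mean_circle=float(c_obs.mean()),
    )
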