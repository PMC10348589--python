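# reachconf

Bayesian observer models of **sensorimotor confidence** in goal-directed
reaching: simulation, maximum-likelihood fitting, BIC model comparison, and
recovery/efficiency studies.

## The problem

After reaching toward a target with an unseen hand, how confident should you
be that you hit it — and which cues feed that feeling?  Two temporally
distinct sources are available: *prospective* cues, known before the movement
(your own motor variability), and *retrospective* cues generated by the
movement itself (the proprioceptively sensed endpoint).  `reachconf`
implements a two-task paradigm that separates them:

* **Control motor-awareness task** — repeated reaches to a fixed target; the
  observer indicates the perceived endpoint, exposing proprioceptive
  reliability.
* **Main confidence-judgment task** — trials arrive in triplets (two reaches
  with endpoint feedback, then one confidence report).  Confidence is
  reported as the radius of a circle centered on the target: the trial is
  rewarded if the circle captures the endpoint dot, with points falling
  linearly from 10 (radius ≤ 2.5 mm) to 0 (radius ≥ 70 mm), so small circles
  are worth more but risk missing.

## The models

An observer is three noise magnitudes **Θ = (σ_m, σ_p, σ_s)**: motor scatter
of endpoints around the target *t* (e ~ N(t, σ_m² I)), proprioceptive noise
on the sensed location (p ~ N(e, σ_p² I)), and Gaussian setting noise on the
reported circle radius.  With reliabilities r_m = 1/σ_m², r_p = 1/σ_p², the
three confidence models differ only in the posterior belief over the
endpoint:

| model | posterior mean | posterior SD |
|---|---|---|
| ideal | ê = (r_m t + r_p p)/(r_m + r_p) | (r_p/(r_p+r_m))·σ_p (`"weighted"`), or 1/√(r_m+r_p) (`"bayes"`) |
| retrospective | p (flat prior) | σ_p |
| prospective | t (ignores p) | σ_m |

Each model sets the circle radius s_c maximizing expected gain
EG(s_c) = f(s_c) · P(‖e − t‖ ≤ s_c + r_dot), where f is the linear reward
ramp and the capture probability is a Rice CDF (the belief is an isotropic
Gaussian, so the distance of e from t is Rice-distributed).  The intended
radius is then perturbed by N(0, σ_s²).

Fitting maximizes the joint log-likelihood of both tasks (endpoint scatter,
indicated endpoints, and circle settings), marginalizing the unobserved
sensed location per confidence trial — by a 2-D grid, or equivalently and
faster by 1-D Gauss–Legendre quadrature over the sensed distance (Rice
density).  All three models carry the same three parameters, so BIC
comparison reduces to log-likelihood comparison.

## Worked example

Simulate an ideal observer (σ_m = σ_p = 20 mm, σ_s = 5 mm) performing both
tasks, fit all three models, and compare them:

```python
import reachconf as rc

params = rc.ObserverParams(sigma_m=20.0, sigma_p=20.0, sigma_s=5.0)
control = rc.simulate_control_task(params, n_trials=300, seed=11)
main = rc.simulate_main_task(rc.ModelKind.IDEAL, params, n_triplets=300, seed=12)

fits = [rc.fit_model(m, control, main,
                     rc.FitConfig(n_starts=2),
                     rc.IntegrationConfig(radial_nodes=64, policy_table_step=2.0))
        for m in (rc.ModelKind.IDEAL, rc.ModelKind.RETROSPECTIVE,
                  rc.ModelKind.PROSPECTIVE)]
table = rc.compare_models(fits)
print(table.to_frame().round(2).to_string(index=False))
print("winner:", table.winner.value)
```

prints

```
        model    loglik      bic  delta_bic
        ideal -13843.88 27709.70       0.00
retrospective -14051.25 28124.43     414.73
  prospective -13878.42 27778.78      69.08
winner: ideal
```

The generating (ideal) model wins decisively: ΔBIC ≈ 69 over the prospective
model and ≈ 415 over the retrospective one (ΔBIC > 10 is conventionally
strong evidence).  The fitted parameters land on the generating values
(σ̂_m = 20.07, σ̂_p = 20.42, σ̂_s = 4.32), and the behavioral summary shows
the ideal signature — confidence circles that track trial-by-trial error
(`rc.behavioral_summary(main)`: capture fraction 0.69, mean circle 29.5 mm,
error–confidence Pearson r = 0.34, p = 2.1e-09).  A prospective observer
would instead produce a near-zero correlation, because its intended circle
is the same on every trial.

The same pipeline is scriptable from the shell:

```bash
reachconf simulate --model ideal --seed 7 --out out/sim
reachconf fit --model all --control out/sim/control_trials.csv \
              --main out/sim/main_trials.csv --out out/fits
reachconf recover-models --n-sets 20 --seed 1 --out out/recovery
```

## Layout

```
src/reachconf/
  task.py        geometry, reward ramp, capture rule
  observers.py   posterior beliefs, Rice capture probabilities, optimal circles
  simulate.py    generative model of both tasks + log-normal parameter priors
  fitting.py     joint likelihoods, latent-location marginalization, ML fits
  evaluate.py    BIC comparison, recovery studies, efficiency, summaries, PPC
  io.py, cli.py  run configs, CSV schemas, reproducible CLI stages
```

See `docs/methods.md` for modeling assumptions, numerical choices, and known
limitations.
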