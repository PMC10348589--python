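# Methods

## Generative model

An observer aims at a target **t** and lands at **e** ~ N(t, σ_m² I): motor
noise is isotropic, unbiased, and independent of target direction.
Proprioception returns **p** ~ N(e, σ_p² I).  Target location is treated as
known exactly (visual uncertainty about the target is assumed negligible
relative to σ_m and σ_p).

*Control task.*  The target sits 150 mm straight ahead on every trial.  The
observer reports the maximum-a-posteriori endpoint estimate
**i** = w_p **p** + (1 − w_p) **t** with w_p = r_p/(r_p + r_m),
r_x = 1/σ_x².  Given (e, t), the indicated endpoint is exactly Gaussian with
SD w_p·σ_p, which the control-task likelihood uses in closed form.

*Main task.*  Targets occupy six sectors on a 183 mm arc (15°–165° in 30°
steps), each sector appearing once per six trials in random order, with
per-axis Gaussian jitter of SD 15 mm.  Trials come in triplets — two
feedback reaches, then one confidence report — so 900 trials contain 300
confidence reports (3 sessions × 100 triplets by default).  On confidence
trials the observer forms a belief over **e** (see below), sets the circle
radius maximizing expected gain, and the realized radius adds setting noise
N(0, σ_s²), redrawn until non-negative.  The likelihood deliberately keeps
the *untruncated* normal density for circle settings: the truncation is a
physical constraint of the apparatus, not part of the observer model, and
with realistic parameters (optima ≳ 20 mm, σ_s ≈ 5 mm) the truncated mass is
negligible.

## Confidence models

All three observers maximize expected gain
EG(s_c) = f(s_c) · P(‖e − t‖ ≤ s_c + r_dot | belief), where f falls linearly
from 10 points (radius ≤ 2.5 mm) to 0 (radius ≥ 70 mm) and r_dot = 2.25 mm
is the endpoint-dot radius (the 4.5 mm figure for the dot is taken as a
diameter; both the dot radius and the intersect-vs-enclose capture rule are
configurable).  Beliefs are isotropic Gaussians, so the distance of **e**
from **t** is Rice-distributed and the capture probability is a Rice CDF
with offset ‖mean − t‖ and scale equal to the belief SD; beliefs narrower
than 1e−9 mm are clamped to keep the CDF defined.

* **Ideal**: mean ê (MAP combination), SD per one of two conventions.  The
  default `"weighted"` convention uses SD w_p·σ_p; the `"bayes"` switch uses
  the product-of-Gaussians width 1/√(r_m + r_p).  The two differ by the
  factor √(r_p/(r_p + r_m)): `"weighted"` is always narrower, i.e.
  overconfident relative to the exact posterior, and as σ_p → ∞ it collapses
  to zero rather than to σ_m.  Both are provided because the weighted form
  is the one the task model is usually written with, while the Bayes form is
  the actual posterior; fitting and simulation default to `"weighted"`,
  and analyses that rely on the ideal observer being a true
  expected-gain maximizer (the efficiency study, the single-cue limit
  checks) use `"bayes"` — under `"weighted"` the "ideal" observer with
  σ_p = 45 mm earns *fewer* points than a prospective-only observer, which
  contradicts the intended meaning of "ideal".
* **Retrospective**: flat prior; belief N(p, σ_p² I).
* **Prospective**: ignores p; belief N(t, σ_m² I), hence one intended circle
  for all trials.

Because all beliefs are isotropic with means on the target→p ray, the
optimal circle depends on p only through d = ‖p − t‖; policies are computed
radially and, where tabulated, interpolated linearly over d.

*Circle search.*  The optimum is the argmax of EG over a radius grid
spanning 0–80 mm at 0.1 mm (80 mm safely brackets the 70 mm zero-reward
point), ties broken to the smallest radius.  Vectorized callers use a
two-stage scan (1 mm coarse pass, then the 0.1 mm grid within one coarse
cell of the coarse argmax); EG is unimodal in the radius for these beliefs
and the two-stage result is unit-tested to equal the brute-force argmax.
If EG underflows to zero across the whole grid (beliefs far outside the
rewarded region) the smallest radius is returned with a warning.

## Likelihood and fitting

The joint log-likelihood sums: (1) control endpoints around the target,
(2) control indicated endpoints around their MAP prediction, (3) *all* 900
main-task endpoints around their targets, and (4) the circle-setting terms
over confidence trials.  For the ideal and retrospective models term (4)
marginalizes the unobserved sensed location:

* `2d-grid`: a 41×41 grid spanning ±4σ_p per axis around e_j, weights
  proportional to the bivariate normal density and renormalized to sum to 1
  (renormalization bounds the truncation bias of the plain Riemann sum);
* `1d-radial` (default): Gauss–Legendre quadrature (200 nodes over
  ±4σ_p around ‖e_j − t_j‖, clipped at zero) against the Rice density of
  d — valid because the policy depends on the sensed location only through
  d.  The two schemes agree within 1e−3 nats/trial and both are converged at
  their defaults (halving the resolution moves the log-likelihood by
  < 1e−3/trial).

Per-trial marginals are floored at 1e−300 before taking logs.  The
prospective model needs no marginalization, and its circle terms are
independent of σ_p — σ_p is identified purely by the control task, which is
why the two tasks are fit jointly.

Maximization is derivative-free Nelder–Mead on log-parameters within
[0.5, 200] mm, from 5 starts by default: one at method-of-moments estimates
(σ_m from pooled endpoint scatter; σ_p by inverting the MAP weight estimated
by regressing indicated on true endpoints; σ_s from the circle-radius SD)
and the rest log-normally jittered around it (SD 0.3 in log space, seeded).
The Gaussian terms are evaluated from precomputed sufficient statistics, so
each objective evaluation costs one policy table plus the quadrature.

## Study sizes and scaled settings

The canonical study design is 300 control trials and 900 main trials (300
confidence reports), with recovery parameters drawn from log-normal priors
with (mean, variance) σ_m (20, 25), σ_p (35, 400), σ_s (7, 25) mm(²);
alternative σ_p presets (40, 200) and (20, 200) are provided, the first
triple being the default.  Large fitting studies (model recovery at 20
draws × 3 models, parameter recovery at 20 self-fits per model) run with a
scaled integration configuration — 64 radial nodes, 2 mm policy-table step,
2 optimizer starts — chosen once as the package's standard batch setting;
it tracks the default configuration to ~2e−5 nats/trial and leaves recovery
results indistinguishable, while keeping a full model-recovery study at a
few minutes on one CPU.

## Efficiency study

Three hypothetical observers share σ_m = 20 mm and σ_s = 5 mm: a
prospective-only observer and two ideal observers with σ_p = 20 or 45 mm.
Each is simulated for 10⁵ confidence trials (Monte-Carlo SE of points/trial
< 0.01) and scored with the task reward and capture rule; efficiency is the
ratio of prospective to ideal mean points per trial.  The ideal policies use
the `"bayes"` width (see above).  Two structural features of this reward
landscape are worth noting: it is flat near the optimum, so with
σ_p = σ_m the retrospective cue buys only a few percent of expected points
(≈97% efficiency) and essentially nothing at σ_p = 45 mm; and the
noise-free "oracle" reference (smallest capturing circle) must be simulated
without setting noise, because a boundary-tight circle misses on half the
setting-noise draws.

## What the generator does and does not emulate

The synthetic data reproduce the trial structure (triplets, sector cycling,
jitter), the noise chain e → p → circle, and the latent-variable structure
that the likelihood marginalizes.  They do not include: practice blocks or
learning of σ_m across trials, reaction-time trial rejection, anisotropic or
biased motor noise (real reach scatter is only approximately isotropic),
memory decay of the proprioceptive trace between reach and report, or
risk-sensitive circle-setting strategies.  Passing recovery tests therefore
demonstrate that the estimation machinery is consistent under the model's
own assumptions — not that real reaching data satisfy those assumptions.

## Numerical and edge-case choices

* Capture rule: center distance ≤ circle radius + dot radius ("intersect or
  enclose"); a strict-enclosure variant is a one-line geometry change.
* Policy tables span 0–300 mm of sensed distance (step 0.5 mm by default);
  beyond the table the policy is held at its last value.
* Degenerate inputs: non-positive σ's, negative radii/distances, empty
  datasets, confidence rows without circles, and out-of-range sectors all
  raise; constant circle vectors in the behavioral summary set a degeneracy
  flag (r = 0, p = 1) rather than returning NaN.
* All randomness flows through `numpy.random.Generator`; simulation stages
  are bit-reproducible under (config, seed), and the CLI derives per-stage
  seeds from one master seed.
* BIC uses n = control trials + main endpoints + confidence settings
  (n = 1500 at the canonical design); since all models share k = 3, n is
  irrelevant to selection and is fixed only for reporting.

## Known limitations

* The `"weighted"` ideal width is kept as the default for fitting even
  though it is not the exact posterior; switching conventions changes the
  ideal policy and hence fitted σ_p slightly.
* The likelihood treats the policy as deterministic given d; observers with
  trial-varying decision noise in the *policy* (rather than the setting)
  would be absorbed into σ_s.
* Model recovery under this machinery is very clean (≥ 90% with the default
  priors); datasets generated with σ_p well above 60 mm are the main source
  of ideal↔prospective confusion, since proprioception is then uninformative
  for gain maximization.
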