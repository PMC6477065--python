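# Methods

This note documents the models, the defaults and the numerical choices the
package makes, and what its synthetic data can and cannot establish.

## Task model

A session is an ordered list of blocks, each with a length and a single
contingency parameter `p_match`: the probability that the reference
association (high tone → female face, equivalently low tone → male face)
holds on a trial. Both cue types share one contingency, so the learner
tracks a single probability — this is what makes the one-dimensional
second level of the HGF the right state. The binary input to all learning
models is the match indicator `u ∈ {0,1}`, a deterministic function of
(cue, outcome).

The canonical session has 150 trials in 10 blocks with lengths
(15, 16, 11, 17, 14, 16, 15, 13, 17, 16) and `p_match`
(0.5, 0.9, 0.1, 0.7, 0.3, 0.9, 0.5, 0.1, 0.7, 0.5). The exact published
block order is not recoverable from text, so this fixed stand-in was
chosen once to attain the stated length extremes (11 and 17), use all
three contingency levels and both complements, and start/end at chance.
Cues are fair-coin i.i.d.; no cue base-rate information exists to suggest
otherwise. Trial indices are 1-based everywhere.

## Learning models

**Three-level binary HGF.** Generative form: x₁ ~ Bernoulli(s(x₂)),
x₂ ~ N(x₂⁻, exp(κx₃ + ω₂)), x₃ ~ N(x₃⁻, exp(ω₃)), with s the logistic
sigmoid. The filter implements the standard single-sweep
prediction/update equations of the binary HGF (the variational inversion
used by the established toolbox lineage): per trial,

- predictions: μ̂₂ = μ₂, μ̂₃ = μ₃, μ̂₁ = s(μ̂₂);
- precision predictions: π̂₂ = 1/(σ₂ + exp(κμ̂₃ + ω₂)),
  π̂₃ = 1/(σ₃ + exp(ω₃));
- level 2: δ₁ = u − μ̂₁, π₂ = π̂₂ + μ̂₁(1−μ̂₁), μ₂ = μ̂₂ + δ₁/π₂;
- level 3: v₂ = exp(κμ̂₃ + ω₂), w₂ = v₂·π̂₂,
  δ₂ = (σ₂ + (μ₂−μ̂₂)²)·π̂₂ − 1,
  π₃ = π̂₃ + (κ²/2)·w₂·(w₂ + (2w₂−1)δ₂),
  μ₃ = μ̂₃ + (κ/2π₃)·w₂·δ₂.

A non-positive updated precision (possible at high ω₂ with κ > 0) raises
an inadmissibility error; the fitting objective maps it to a large finite
value so optimizers retreat. κ is fixed (default 1.0) — its published
value is unavailable, and freeing it is explicitly out of scope. Initial
states default to μ₂⁰ = 0, σ₂⁰ = 0.1, μ₃⁰ = 1, σ₃⁰ = 1 (toolbox
convention); all are configurable.

**Rescorla–Wagner.** v ← v + α(u − v) with fixed learning rate
α ∈ (0,1), v₀ = 0.5.

**Sutton K1.** Gain adaptation for the single predictor: the log learning
rate β follows the correlation between the prediction error and an
eligibility trace h: β ← β + μ_meta·δ·h, α = min(exp β, 1),
v ← v + αδ, h ← (h + αδ)·max(0, 1−α), h₀ = 0. Defaults: β₀ = ln 0.1
fixed, μ_meta free — a deliberately two-free-parameter competitor
(μ_meta, ζ), stable under the α ≤ 1 cap. The published free-parameter
set for this competitor is in an unavailable supplement; these defaults
are declared, not inferred.

**Response model.** All three models map the one-step-ahead outcome
prediction μ̂₁ through the unit-square sigmoid
p(y=1) = μ̂₁^ζ/(μ̂₁^ζ + (1−μ̂₁)^ζ), computed in log space for stability.
Sharing the response family across models keeps their evidences
comparable. Missing responses contribute nothing to the likelihood but
the input still updates beliefs. μ̂₁ is clipped to [10⁻⁴, 1−10⁻⁴] in the
likelihood so the log stays finite.

## MAP inversion and Laplace evidence

Free parameters are estimated in an unconstrained space — identity for
ω₂, ω₃; log for ζ and μ_meta; logit for the RW α — under independent
Gaussian priors: ω₂ ~ N(−3, 4²), ω₃ ~ N(−6, 4²), ln ζ ~ N(ln 48, 1),
logit α ~ N(logit 0.3, 1), ln μ_meta ~ N(ln 0.05, 1). The study's own
priors are unavailable; these follow toolbox conventions and are fully
configurable through `PriorSpec`.

The objective is the negative log joint. Optimization is the best of
`n_restarts` (default 8) L-BFGS-B runs: the first start at the prior
mean, the rest prior-dispersed (mean + SD·z), with restart draws derived
from one master seed so runs reproduce exactly. Convergence tolerance is
10⁻⁶ on the objective.

Log model evidence is the Laplace approximation
−nlj(θ̂) + (d/2)ln 2π − ½ ln det H with H the central-difference Hessian
(step 10⁻⁴ in estimation space). Positive definiteness is checked by
Cholesky; failures flag the fit rather than fabricate an evidence. The
same estimation-space convention is used for fitting and evidence, which
is the invariance the comparison across models relies on; on the
conjugate Gaussian test case the approximation is exact to the Hessian's
discretization error.

Parameter recovery simulates `n_sims` sessions per subject from the
fitted (or true) parameters, refits each, averages the recovered values,
and reports the per-parameter Pearson correlation between original and
mean-recovered values across subjects.

## Random-effects model selection

The subjects × models log-evidence matrix feeds a variational Dirichlet
model over population model frequencies: iterate
g_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα)), α = α₀ + Σₙ gₙ, to a 10⁻⁶
fixed-point tolerance (α₀ = 1 per model). Exceedance probabilities are
Monte-Carlo frequencies of argmax under Dirichlet(α) (default 10⁵
seeded draws; exact ties broken by an infinitesimal uniform jitter). The
omnibus risk compares the variational free energy F1 (including the
closed-form Dirichlet KL) against the equal-frequency null
F0 = Σₙ[logsumexp_k L_nk − ln K]: bor = 1/(1+exp(F1−F0)), and protected
exceedance probabilities shrink toward 1/K: pxp = ep·(1−bor) + bor/K.

## Cohort statistics

- Summaries report sample SD (n−1), adjusted Fisher–Pearson skewness and
  *excess* kurtosis; constant variables get NaN markers, not exceptions.
- The Tukey ladder searches λ ∈ {−2, −1, −½, 0 (log), ⅓, ½, 1, 2}, adds
  a +1 offset when min(x) ≤ 0, negates negative-power rungs to keep the
  transform increasing, minimizes |sample skewness| and breaks ties
  toward λ = 1. The criterion is declared here because the original λ is
  unstated.
- Pearson p-values use the t reference with n−2 df; VIF is 1/(1−R²) from
  OLS of each predictor on the rest, with exact collinearity flagged as
  infinite rather than crashing.
- The regression suite is fixed: simple (transform + ω₂), full (plus
  interaction), and the two partial models with the interaction. OLS via
  statsmodels; t-based 95% CIs; Q² = 1 − PRESS/TSS by explicit
  leave-one-out refits. Anxiety scores are deliberately not regression
  predictors; they enter only the graphical model.
- The mixed graphical model is pairwise, estimated nodewise: lasso for
  continuous nodes (internally standardized), L1 logistic regression for
  binary 0/1 nodes, over a 50-point log-spaced λ grid from each node's
  λ_max down by 10⁻³. The lasso path proposes candidate supports; each
  support is scored by EBIC (γ = 0.25) on its *unpenalized ML refit* —
  the likelihood the criterion is defined for — because scoring shrunken
  coefficients lets weak noise predictors ride in on the improving fit
  of strong ones as λ decreases. Edges require nonzero coefficients in
  both directions (AND rule); the weight is the signed mean of the two
  refit coefficients, zero on sign conflict.

## Synthetic cohort generator

The generator encodes the study conditions: 36 subjects by default, the
published questionnaire structure (15 verbal-abuse items per developmental
period scored 0–8; three 4-item resilience subscales scored 1–5; two
20-item anxiety forms scored 1–4) and the published moments.

Each variable is a monotone transform of a standard-normal latent in a
Gaussian copula. Raw verbal-abuse period scores are zero-inflated
lognormal before integer clipping (zero-inflation 0.25/0.15/0.12 and
log-body parameters chosen once to match the published medians and means,
which are strongly right-skewed); resilience and anxiety scales are
rounded clipped Gaussians at their published moments; ω₂ ~ N(−5.46,
2.82²) clipped to [−12, −1.5] — the upper clip keeps every agent inside
the filter's admissible regime at κ = 1 — ω₃ ~ N(−6.06, 0.14²), and ζ
lognormal matched to mean 3.16, SD 1.94.

For each configured correlation pair the latent correlation is calibrated
by Gauss–Hermite quadrature plus root finding so the *output-scale*
Pearson correlation hits its target despite the nonlinear marginals
(defaults: ω₂ with childhood −0.379 and adolescent −0.448 verbal-abuse
scores; pairs without a published value default to 0). The matrix is
repaired to the nearest positive-definite correlation if needed.

The emotion-coping subscale is structural, not copula-drawn:
ras_emotion = 15.072 − 0.891·vaq_preschool_t − 0.282·ω₂ + N(0, 2.281²),
rounded and clipped to [4, 20], with vaq_preschool_t the ladder transform
of the raw preschool score linearly rescaled to mean 1.31, SD 0.98 — the
scale on which the published coefficients are defined (Pearson structure
is invariant to the rescaling). Item-level scores are random integer
compositions of each total within the item range; only totals feed the
analysis. Behavior is one canonical 150-trial session per subject,
simulated from that subject's HGF parameters.

**What the generator does not emulate:** real response times, attention
lapses and missing responses (simulated agents always answer), any
non-HGF generative heterogeneity across subjects, demographic structure
beyond marginal moments, and the unknown true joint law between the
preschool score and ω₂ (defaulted to independence in the copula). Tests
passing on this cohort show the pipeline is correct and well-calibrated
under its assumed effect structure, not that the effect structure holds
in new empirical data.

## Problem sizes and tolerances

The test suite uses the study-scale designs directly where they are
cheap (36 subjects, 150 trials, 500-cohort regression recovery) and
reduced restart counts (2–4) for the many-hundreds-of-fits simulation
studies, which the recovery and selection margins comfortably tolerate.
Monte-Carlo assertions use 3-standard-error bands around their exact
oracles. The ignored-free-parameter evidence check asserts equality, not
a decrease: a parameter the likelihood ignores, under a Gaussian prior,
integrates to one exactly and the Laplace approximation reproduces that,
so no complexity penalty can appear.

## Known limitations

- The Laplace evidence is a local approximation; multimodal posteriors
  (possible at extreme ζ) are summarized by the best mode found.
- ω₃ is weakly identified from 150 binary trials — recovery correlations
  for ω₃ are reported but not asserted, and its tight between-subject SD
  in the generator reflects the published summary, under which sampling
  variation dominates.
- The mixed graphical model's AND rule is conservative by construction;
  with 36 subjects only strong conditional associations survive.
- The κ-free HGF variant is intentionally not implemented.
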