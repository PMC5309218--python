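# Methods

## Model

Each of six cartoon characters carries a scalar expected value `V_c ∈ [0, 1]`
tracking its learned reward anticipation. Values start at `V0` and are updated
after every trial's binary feedback `r ∈ {0, 1}` by the delta rule

    δ(t) = r(t) − V_c(t),        V_c(t+1) = V_c(t) + α·δ(t),

with learning rate `α ∈ [0, 1]`. Because feedback is predetermined and
choice-independent, no choice policy (softmax etc.) exists or is modeled; the
delta rule is pure Pavlovian value tracking. Values are tracked per character,
not per object pair, and reset between sessions (each session uses fresh
characters, so carry-over has nothing to attach to).

Memory encoding is modeled as a Bernoulli event per trial: the later test
outcome `y(t) ∈ {0, 1}` (hit/miss for that trial's character–object pair) has
probability `p(t) = logistic(R(t))`, where the reward signal `R(t)` is a
linear combination of that trial's *pre-update* value `V_c(t)` and its *own*
prediction error `δ(t)` (both indexed at `t`):

    R(t) = C0 + C_δ·δ(t) + C_|δ|·|δ(t)| + C_V·V_c(t)

Six nested variants free different subsets of the scale factors (see README
table). The parameter count `k` is C0 plus the free scale factors plus `α`
whenever any value/PE term is present; these counts (1/3/3/4/4 across the
non-baseline models) are locked to the published fit table through the exact
identity `AIC = 2k + 2·LLE`, which the test suite checks against every
published row.

## Parameters and bounds

| parameter | meaning                            | bounds   | default |
|-----------|------------------------------------|----------|---------|
| C0        | encoding offset (logit units)      | [−2, 2]  | fitted  |
| C_δ       | signed-PE weight                   | [−2, 2]  | fitted  |
| C_\|δ\|   | unsigned-PE ("surprise") weight    | [−2, 2]  | fitted  |
| C_V       | expected-value weight              | [−2, 2]  | fitted  |
| α         | learning rate                      | [0, 1]   | fitted  |
| V0        | initial expected value             | [0, 1]   | 0.5     |

`V0 = 0.5` is the neutral midpoint between the two outcome values; it is a
config field (and CLI-reachable) so 0 can be explored too. Under these bounds
`|R| ≤ 6`, so `p ∈ [0.0025, 0.9975]` and the log-likelihood is always finite —
no epsilon-clamping is ever needed.

## Fitting

Per participant and per model, the negative log-likelihood
`LLE = −Σ_t [y log p + (1−y) log(1−p)]` over the session's 60 trials is
minimized in two stages:

1. **Exhaustive grid.** Default steps 0.1 for scale factors and 0.05 for α.
   A literal 0.01-step grid over four parameters would have ~6.5×10⁹ points;
   the coarse default (≈1.4×10⁶ points for the largest model) preserves the
   two-stage structure at desk scale, and the 0.01 grid remains available via
   `FitOptions` for models with few free parameters, guarded by an explicit
   evaluation budget that names the coarser default when exceeded. The grid
   pass is vectorized through the identity
   `LLE = Σ softplus(−R) + Σ (1−y)·R` with `R` linear in the scale factors at
   fixed α, evaluated in float32 (`grid_dtype` option; ~3× faster, worst-case
   NLL error ~4×10⁻⁵ on 60 trials). Ties break to the first minimum in
   (α ascending, scale factors lexicographic) order, deterministically.
2. **Nelder–Mead refinement** inside a box of one grid step around the grid
   optimum, intersected with the global bounds and enforced by clipping
   candidate vertices; float64 throughout; function tolerance 1e−8, max 2000
   evaluations. The refinement radius equals the grid step rather than a
   fixed ±0.01, because a ±0.01 box around a 0.1-step grid optimum would be
   vacuous. The stage never returns a point worse than its start.

`AIC = 2k + 2·LLE` compares models; the winner is the minimal cohort-mean
AIC, with paired sign-flip tests of per-participant AIC differences reported
alongside (significance is reported, not required, for the label). Mean-AIC
ties break to fewer parameters, then fixed name order.

## Synthetic cohorts

The generator inverts the likelihood: outcomes are independent Bernoulli
draws from the generative `p(t)`. Defaults encode the study conditions: 60
trials per session (6 characters × 10 trials, 8/5/2 positive feedbacks for
high/medium/low anticipation, block order and feedback positions uniformly
random per seed), 25 participants per cohort, generative parameters either
fixed at the published group means or sampled per participant from truncated
Gaussians centered there with SD = published SEM·√25.

Confidence ratings are drawn from a 3-level categorical whose
"certain"-share rises across terciles of the participant's `p(t)` — a
monotone stochastic mapping chosen because the behavioral phenomenon to
reproduce is ordinal (certain > quite certain > guess accuracy). Trait
scores (SR/SP) are coupled to any per-participant statistic through a
Gaussian copula on ranks; the latent correlation is calibrated by inverting
the exact bivariate-normal expectation of the sample Spearman coefficient,
`E[r_s] = 6/(π(n+1))·[asin(ρ) + (n−2)·asin(ρ/2)]`, so the target rank
correlation is hit in expectation at the cohort's actual n (a naive
`2·sin(πρ_s/6)` mapping under-shoots by ~0.03 at n = 19). SR and SP share a
common nuisance component so neither raw scale alone carries the coupling.

What the generator does **not** emulate: sleep/consolidation differences
between the 20-min and 24-h delays (delays differ only through their
generative parameter sets); any real-data idiosyncrasy such as
medium-ratio final values sitting above the neutral expectation; response
times, stimulus identity, or the practice session. Passing tests therefore
demonstrate internal consistency of the estimation machinery under the
stated generative assumptions, not fidelity to unpublished raw data.

## Statistics

Permutation tests are two-sided sign-flip Monte-Carlo tests with 10,000
permutations by default, mandatory seeds, and the add-one correction
`p = (#{|perm| ≥ |obs|} + 1)/(n_perm + 1)` (so `p ≥ 1/(n_perm+1)` and the
test is valid at any `n_perm`). Condition means are computed per participant
first (the participant is the unit), then averaged with SEM; empty design
cells surface as missing rows, never silently dropped. Character-level
regression slopes use OLS on level codes −1/0/+1 (any affine recoding only
rescales slopes), computed per participant and then averaged — the
per-participant-first choice, and the level coding, are conventions the
original analysis leaves open. The sensitivity bias is z(SR) − z(SP) with
cohort mean/SD (ddof = 1), so it is zero-mean by construction; Spearman ρ
uses mid-ranks.

## Problem sizes used by the test suite

Simulation-based checks run at sizes chosen to make their claims decidable
at desk scale: parameter recovery at the full 200 participants on the
default grid; model recovery over 10 replicate cohorts of n = 25 at grid
steps 0.2/0.1; the overfitting control over 100 baseline-generated cohorts
at steps 0.25/0.125 (the claim — that the AIC penalty blocks spurious wins
of the richer model — is insensitive to grid resolution); type-I calibration
over 2500 null datasets with 400 permutations per test, cross-checked
against the exact t-test on the identical data.

## Known limitations

- **Model identification at 60 trials is intrinsically weak.** At the
  published group-mean effect sizes, the expected likelihood advantage of
  the true δ+V generative model over a refitted constant-rate baseline is
  only ≈1.25 nats per 60-trial session — smaller than the AIC penalty gap to
  the nested 3-parameter models. AIC model recovery on such sessions
  therefore fails (the nested δ model usually wins), and the corresponding
  end-to-end test documents this honestly rather than passing by
  construction. Notably, the published mean baseline LLE (70.755) exceeds
  the largest value a 60-trial baseline fit can attain at its MLE
  (60·ln 2 ≈ 41.6), implying the original fits pooled more than 60
  observations per participant; with only 60 trials per fit, the printed
  effect sizes cannot support reliable AIC selection of the 4-parameter
  model.
- Learning-rate estimates are strongly biased toward the bounds at this
  trial count (fitted α means ≈0.5 when generating at 0.329), and `C_V` is
  partially confounded with `C0` because `V` has limited within-session
  variance around `V0`. Scale-factor recovery of `C_δ` is nevertheless
  accurate to well within ±0.2 at cohort level.
- Fits are point MLEs; no standard errors, hierarchical shrinkage, or
  cross-validation. Repeated-measures ANOVA is deliberately replaced by the
  permutation analogues throughout.
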