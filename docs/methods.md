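# Methods

## Model

The core model is a finite mixture of piecewise latent growth curves for
a bounded symptom score observed on a labelled occasion grid
(screening, registration, biweekly weeks 2–12, post). Subject *i* in
class *k* has growth factors η_i = μ_k + (b_i, 0, 0)ᵀ with
b_i ~ N(0, ψ), and scores y_it = Λ_t η_i + ε_it with ε_it ~ N(0, θ).

Constraints (the "hybrid" structure between a latent-class growth model
and a fully free growth mixture):

- slope variances are identically zero — heterogeneity in change is
  carried by the class mean slopes only;
- one intercept variance ψ, shared across classes;
- one residual variance θ, shared across occasions and classes (a
  per-occasion θ_t would add T−1 parameters against the model's
  parameter-sparsity intent; the flag is reserved but not implemented);
- intercept–slope covariances are forced to zero (implied by zero slope
  variances).

Parameter count: p = (K−1) + 3K + 2.

**Loadings.** The intercept column is 1 everywhere. Slope 1 is 0 at
screening, 1 from registration on. Slope 2 is 0 on the first two
occasions; afterwards it is log₁₀ of the occasion's time index
(2 at week 2, 3 at week 4, …), or the raw index under the `linear`
coding, which exists to let BIC compare the two time codings. The
early-change analysis always fits on the 4-occasion sub-grid
(screening, registration, wk2, wk4), whatever later occasions exist.

**Missing data.** Because the intercept loading is all-ones, the
within-class covariance of any observed sub-vector is compound
symmetric, ψJ + θI. The per-subject marginal log-density therefore has a
closed form via Sherman–Morrison (no matrix factorizations), and
partially observed series contribute through exactly the observed
coordinates — no imputation. Subjects are retained only if the screening
score and at least one of the week-2/week-4 scores are observed; the
loader drops violators with a logged count.

## Estimation

EM over (class membership, intercept deviation b_i):

- E-step: class posteriors from the marginal densities; conditional
  moments of b_i given class and observed data (closed form under
  compound symmetry).
- M-step (conditional): class mean vectors by weighted least squares
  given the old variance components, then ψ and θ in closed form given
  the new means. This expectation–conditional-maximization scheme keeps
  the observed-data log-likelihood non-decreasing; the fitted object
  exposes the trace (`loglik_trace_`) and tests assert monotonicity to
  1e-8.

**Starts.** `n_starts` (default 20) runs: the first from a k-means
partition of (screening, last-observed-early-occasion) pairs, the rest
from that partition with a random 30% of subjects reassigned. A start
whose smallest mixing weight falls below 1/(2n) is discarded as
degenerate; if all starts degenerate the fit raises. Convergence:
relative log-likelihood change < 1e-7 (or 500 iterations, flagged).

**Determinism.** All randomness flows from integer seeds through
`numpy.random.default_rng`; identical (data, spec, seed, n_starts) give
bit-identical fits. Fitted classes are reported in descending-intercept
order so labels are reproducible; posterior ties break toward the lower
class index.

## Class enumeration

Models are fitted for K = 1..K_max (per-K seeds derived from a master
seed). The candidate K is the last before the BIC stops decreasing
(BIC(k+1) ≥ BIC(k); ties stop the ascent). The candidate is confirmed
with a parametric-bootstrap likelihood ratio test of K vs K−1: B
datasets are simulated from the fitted (K−1)-class model with the parent
data's missingness mask reapplied verbatim, both models are refitted on
each, and p = (1 + #{replicate −2ΔLL ≥ observed}) / (B + 1). A
non-significant test steps the procedure down (K−1 vs K−2, …); the
fallback is K = 1. Entropy is reported alongside but never used for
selection.

Cost controls for the bootstrap: replicate refits warm-start from the
parent fit's parameters plus 4 random starts and cap EM at 100
iterations — a documented deviation from full multi-start, acceptable
because the replicate statistic only needs to be comparable to the
observed one, not polished to convergence. A replicate whose refits all
degenerate is redrawn up to 3 times, then counted conservatively as
exceeding the observed statistic. B defaults to 99; note that p cannot
fall below 1/(B+1), so B ≤ 19 can never reject at α = .05 (the selector
warns).

## Reliable change and effect sizes

RCI threshold = z·√2·SD·√(1−r); with the scale's published reliability
r = .86, intake SD = 2.37 and z = 1.96 (two-sided 95%) this is 2.46
points. Improvement/deterioration require the pre–post change to
*strictly* exceed the threshold; a change exactly at it counts as
unchanged. Subjects without both scores are excluded with a logged count
(completer analysis — the source design does not state its handling).
Within-group d = mean(pre − post) / SD of the screening score;
between-group d uses the (n−1)-weighted pooled SD, which reproduces the
published adherence contrasts (0.28, 0.36, 0.44) from the printed group
cells.

## Association statistics

- Contingency: Pearson chi-square with df = (R−1)(C−1) and plain Pearson
  residuals (O−E)/√E — this, not the adjusted (Haberman) residual,
  reproduces the published cell residuals (1.5, −3.00, 7.2). The
  published df for the class-by-outcome table (9) is inconsistent with a
  3×3 table; df is reported as computed (4).
- ANOVA: classical equal-variance decomposition; pairwise pooled-t
  contrasts with Bonferroni multiplication; pooled-SD d per pair.
- Hierarchical regression: blocks enter cumulatively in a stated order;
  after a block enters, its predictors with p > .05 are dropped before
  the next block (single-shot exclusion, with the exclusion t/p
  reported); the final block keeps all entrants. This mirrors the
  described "stepwise" mechanics without a full forward/backward search,
  which is deliberately not implemented. ΔR² and the F-change test are
  computed per step as entered.
- Multinomial logit (statsmodels MNLogit) with Wald SEs, OR = exp(B),
  95% CI = exp(B ± 1.96·SE), model chi-square vs intercept-only,
  Cox & Snell R² = 1 − exp((2/n)(LL₀ − LL₁)) and Nagelkerke rescaling.
  Coefficients above 50 in absolute value flag apparent separation.

## Synthetic data generator

Emulates the design the analysis assumes, with ground truth for testing:

- three classes at proportions (.386, .452, .161)/Σ with intercept means
  (12.08, 8.44, 11.27);
- pre-treatment slopes (0, −1.2, +1.4): flat, improving, worsening —
  the class *shapes* described for the design; early-intervention slopes
  are then solved so the within-class screening→week-4 change equals the
  anchor effect sizes (1.35, 0.98, −1.78) in units of the intake-sample
  SD (2.37);
- within-class variance ψ + θ = 2.37² − (between-class variance of the
  screening means ≈ 2.94) ≈ 2.68, split ψ = 1.8, θ = 0.88 — the intake
  SD is a whole-sample figure, so the within-class spread must be the
  remainder; the split itself is a free choice (only the sum is pinned);
- post score = trajectory endpoint + class shift + noise, solved so the
  mean pre–post change matches the anchors (1.63, 1.25, −0.47)×2.37 and
  the reliable-improvement rates land near 62/56/27%; an attitude
  covariate feeds the post score with a small negative coefficient so
  predictor screening finds r ≈ −.12;
- missingness: occasion-wise independent (MCAR); registration 5%,
  weeks 2/4 20%, later occasions per class so the mean number of
  completed interim assessments matches (2.80, 2.37, 2.27) out of 4; the
  mask is redrawn per subject until the inclusion rule holds. A
  dropout-style monotone mechanism is out of scope (none is described
  for the source design).
- covariates and adherence: class-linked normals chosen to reproduce the
  published between-class effect-size pattern (physical health lowest in
  the deterioration class, mental health highest in the mild class,
  etc.); email support = screening score ≥ 10, the design's rule;
- scores are rounded to integers and truncated to [0, 27] (the scale is
  an integer sum score); tests needing exact Gaussian theory disable
  rounding. The per-occasion rounding/truncation bias is logged and
  stays below 0.2 points at defaults.

What passing tests on this generator do **not** show: robustness to
non-normal within-class distributions, informative (non-MCAR) dropout,
item-level measurement artifacts, or floor effects stronger than the
mild truncation the defaults produce.

## Numerical and design choices

- Entropy: relative entropy 1 − Σ(−p·ln p)/(n·ln K) (any log base
  cancels); NaN for K = 1.
- Recovery checks compare fitted mixing weights to each replicate's
  *drawn* class fractions (the estimable truth for that dataset);
  intercept means are compared to the generating anchors.
- The registration occasion is modelled as a distinct administration of
  the scale, not a carried-over screening value.
- The `linear` slope-2 coding is the raw time index (2, 3, …), the
  natural counterpart the log-linear coding was compared against.
- Problem sizes in the statistical test suite (20 recovery replicates at
  n = 409; 10 enumeration replicates with B = 49; 100 type-I replicates
  at n = 200) are the smallest at which the pass criteria are stable
  across seeds.

## Known limitations

- No per-occasion residual variances, covariance structures beyond the
  hybrid constraints, or Bayesian estimation (out of scope).
- The BLRT's replicate refits are deliberately cheaper than the parent
  fits (see above); with pathological data this could bias replicate
  statistics downward slightly, making the test anti-conservative in
  principle — the type-I simulation bounds this at the design
  conditions.
- Entropy of fitted solutions on default synthetic data (~0.7) is
  somewhat higher than the published 0.65, i.e. the generator's classes
  are slightly better separated than the original sample's.
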