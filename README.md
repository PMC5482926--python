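# earlychange

Piecewise growth mixture modelling of **early symptom change** in
longitudinal intervention data, with the downstream statistics that link
early-change trajectory classes to treatment outcome and adherence.

The package targets a common design in internet-delivered depression
treatment research: patients fill out a symptom scale (e.g. the PHQ-9,
range 0–27) at screening, at registration, every two weeks during a
12-week web intervention, and at post-treatment. The scientific questions
are (i) which latent *patterns* of change over the first four weeks exist,
(ii) how many such patterns the data support, and (iii) whether early
pattern membership predicts end-of-treatment outcome and adherence beyond
intake characteristics.

## The model

For subject *i* in latent class *k*, observed scores follow a latent
growth curve with three growth factors — an intercept, a pre-treatment
slope (screening → registration) and an early-intervention slope
(registration → week 4) —

```
y_i = Λ η_i + ε_i,   η_i = μ_k + (b_i, 0, 0)ᵀ,
b_i ~ N(0, ψ),       ε_it ~ N(0, θ)
```

with fixed loadings Λ: the intercept loads 1 everywhere; slope 1 loads 0
at screening and 1 afterwards; slope 2 loads 0 at screening and
registration and log₁₀ of the occasion's time index afterwards (0.30103
at week 2, 0.47712 at week 4). Slope variances are fixed to zero and ψ, θ
are shared across classes, so heterogeneity in *change* is carried
entirely by the class mean slopes. Partially missing series enter through
the marginal normal density of their observed coordinates
(full-information likelihood). Estimation is multi-start EM.

The number of classes K is chosen by a two-fold rule: increase K until
the BIC stops decreasing, then confirm the candidate against K−1 with a
parametric **bootstrapped likelihood ratio test** (BLRT), stepping down
while the test is non-significant.

Downstream, subjects are classified as reliably improved / deteriorated /
unchanged against the Jacobson–Truax reliable change index
(RCI = z·√2·SD·√(1−r), which is 2.46 PHQ-9 points for r = .86,
SD = 2.37, z = 1.96), and class membership is linked to outcome and
adherence via chi-square tests with Pearson standardized residuals,
one-way ANOVAs with Bonferroni post hocs, hierarchical regression and
multinomial logistic regression.

Because the original trial data are not publicly deposited, the package
ships a synthetic-data generator (`earlychange.simulate`) that emulates
the study design — three latent classes at proportions .386/.452/.161
with screening means 12.08/8.44/11.27, calibrated early-change effect
sizes, class-linked covariates and adherence, and the study's
missingness/inclusion pattern — with ground-truth labels for every test.

## Worked example

```python
import numpy as np
from earlychange import (
    PiecewiseGrowthMixture, build_loading_matrix, early_change_grid,
    default_study_config, generate, compute_rci,
)

ds, truth = generate(default_study_config(n_subjects=409), seed=1)
early = ds.restrict_occasions(["screening", "registration", "wk2", "wk4"])

model = PiecewiseGrowthMixture(
    n_classes=3,
    loading_matrix=build_loading_matrix(early_change_grid()),
    random_state=7,
).fit(early.scores)

print(np.round(model.weights_, 3))   # [0.414 0.135 0.452]
print(np.round(model.means_, 2))     # class (intercept, slope1, slope2)
# [[12.04 -0.02 -7.09]
#  [10.93  1.57  6.15]
#  [ 8.25 -1.03 -2.41]]
print(round(model.bic_, 1))          # 5734.4
print(compute_rci(0.86, 2.37).threshold)  # 2.458... -> 2.46 points
```

The three recovered classes mirror the generating structure: a severe
class that improves steeply once the intervention starts (negative
slope 2, flat slope 1), a deteriorating class (both slopes positive), and
a milder class already improving between screening and registration.

The same analysis end-to-end, from the shell:

```bash
earlychange run --n 409 --k-max 4 -b 99 --seed 1 --out results/run1
```

writes the enumeration table (BIC/SABIC/AIC/entropy/BLRT p per K), the
per-subject posterior and reliable-change tables, and the association
statistics as TSV/JSON plus a readable markdown report.

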