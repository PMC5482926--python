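"""Synthetic-data generator emulating the 12-week web-intervention design.

Generates latent-class piecewise PHQ-9 trajectories on the full occasion
grid (screening, registration, biweekly weeks 2-12, post), together with
class-linked covariates, adherence metrics, a post-treatment outcome, the
study's missingness pattern, and ground-truth labels.

Default conditions follow the published class structure: three latent
classes at proportions .386/.452/.161 with screening means 12.08, 8.44 and
11.27 — an "early response after registration" class (flat pre-treatment
phase, steep early-intervention improvement), an "early response after
screening" class (improvement in both phases from a milder baseline) and
an "early deterioration" class (worsening in both phases).  Phase slopes
are calibrated so the within-class early-change effect sizes (screening to
week 4, in units of the intake-sample screening SD 2.37) hit the published
anchors d = 1.35, 0.98 and -1.78, and the post score is calibrated so
pre-post effect sizes and reliable-improvement rates land near the
published 1.63/1.25/-0.47 and 62/56/27% patterns.  Within-class variances
are free parameters (not published); they are chosen so the *whole-sample*
screening SD matches the published intake SD of 2.37 — the within-class
variance is that total variance minus the between-class variance of the
screening means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import LongitudinalDataset
from .grids import OccasionGrid, build_loading_matrix, default_grid

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "GroundTruth", "default_study_config", "generate"]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; defaults come from
    :func:`default_study_config`."""

    n_subjects: int
    class_proportions: tuple  # sums to 1
    intercept_means: tuple  # per class
    slope1_means: tuple  # pre-treatment phase slope per class
    slope2_means: tuple  # early-intervention slope (log-linear time scale)
    intercept_var: float  # psi
    residual_var: float  # theta
    grid: OccasionGrid
    transformation: str = "log_linear"
    # missingness: per-occasion base probability; late occasions (after wk4)
    # get per-class probabilities so assessment counts are class-linked
    missing_prob: dict = field(default_factory=dict)
    late_missing_by_class: tuple = (0.30, 0.41, 0.43)
    # outcome model
    post_shift: tuple = (0.0, 0.0, 0.0)  # class shift of post vs trajectory end
    post_noise_sd: tuple = (1.0, 1.0, 1.0)
    apoi_outcome_coef: float = -0.9  # attitude -> post score slope
    # covariates: per-class (mean, sd) for each named scale
    covariate_model: dict = field(default_factory=dict)
    # adherence: per-class (mean, sd)
    modules_model: tuple = ((9.84, 3.90), (8.64, 4.52), (8.65, 4.85))
    hours_model: tuple = ((8.36, 4.08), (7.32, 4.69), (8.33, 6.39))
    support_threshold: float = 10.0  # email support iff screening >= threshold
    round_scores: bool = True

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("class proportions must sum to 1")
        # theta = 0 is allowed here (noise-free generation for exactness
        # checks); the fitted model itself requires theta > 0
        if self.intercept_var < 0 or self.residual_var < 0:
            raise ValueError("variances must be non-negative")
        for v in self.missing_prob.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError("missingness probabilities must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)


@dataclass
class GroundTruth:
    """Per-subject generating truth, aligned with the emitted dataset."""

    classes: np.ndarray  # (n,) 0-based true class
    growth_factors: np.ndarray  # (n, 3) intercept, slope1, slope2
    latent_scores: np.ndarray  # (n, T) noiseless class curves + intercept dev
    raw_scores: np.ndarray  # (n, T) noisy scores before rounding/truncation


# published anchors used for calibration -----------------------------------
_PROPORTIONS = (0.386, 0.452, 0.161)
_INTERCEPTS = (12.08, 8.44, 11.27)
_EARLY_D = (1.35, 0.98, -1.78)  # screening -> wk4, screening-SD units
_PREPOST_D = (1.63, 1.25, -0.47)
_IMPROVED_FRAC = (0.62, 0.56, 0.27)
_SLOPE1 = (0.0, -1.2, 1.4)  # flat / improving / worsening pre-treatment phase


def default_study_config(n_subjects: int = 409, round_scores: bool = True) -> GeneratorConfig:
    """Generator configuration reproducing the study's class structure.

    Phase-2 slopes are solved from the early-change effect-size anchors:
    with wk4's log-linear loading l = log10(3) and the intake-sample SD
    s = 2.37 the effect sizes are expressed in,
    slope2 = -(d_early * s + slope1) / l.  The post-score shift and noise
    are solved the same way from the pre-post effect sizes and
    reliable-improvement rates (improvement threshold 2.46 scale points).
    """
    # effect-size anchors are in units of the intake-sample screening SD
    scale_sd = 2.37
    # within-class variance: that intake SD is a whole-sample figure, so
    # psi + theta = 2.37^2 minus the between-class variance of the
    # screening means (~2.94) ~= 2.68
    psi, theta = 1.8, 0.88
    grid = default_grid()
    lam = build_loading_matrix(grid, "log_linear")
    l_wk4 = lam.values[grid.index("wk4"), 2]
    l_post = lam.values[grid.index("post"), 2]

    props = np.asarray(_PROPORTIONS) / np.sum(_PROPORTIONS)
    slope1 = np.asarray(_SLOPE1)
    slope2 = -(np.asarray(_EARLY_D) * scale_sd + slope1) / l_wk4

    # post = trajectory endpoint + shift + noise; mean change pins the shift,
    # the reliable-improvement rate pins the change SD
    latent_change = -(slope1 + l_post * slope2)  # mean(screening - post), latent
    target_change = np.asarray(_PREPOST_D) * scale_sd
    post_shift = latent_change - target_change
    rci_threshold = 2.46
    z = norm.ppf(1.0 - np.asarray(_IMPROVED_FRAC))
    change_sd = (rci_threshold - target_change) / z
    post_noise_sd = np.sqrt(np.maximum(change_sd**2 - theta, 0.25))

    missing = {lab: 0.0 for lab in grid.labels}
    missing.update({"registration": 0.05, "wk2": 0.20, "wk4": 0.20})
    # wk6..wk12 handled per class via late_missing_by_class
    assess_targets = (2.80, 2.37, 2.27)  # mean observed assessments after wk4
    late_miss = tuple(1.0 - m / 4.0 for m in assess_targets)

    covariates = {
        "hrsd24": {"slope_on_screening": 2.0, "noise_sd": 5.0},
        "sf12_physical": {"means": (38.0, 38.5, 34.0), "sd": 10.0},
        "sf12_mental": {"means": (32.0, 39.2, 34.5), "sd": 9.5},
        "fep2": {"means": (2.05, 1.85, 2.06), "sd": 0.48},
        "apoi": {"means": (3.5, 3.5, 3.5), "sd": 0.6},
    }
    return GeneratorConfig(
        n_subjects=n_subjects,
        class_proportions=tuple(props),
        intercept_means=_INTERCEPTS,
        slope1_means=tuple(slope1),
        slope2_means=tuple(slope2),
        intercept_var=psi,
        residual_var=theta,
        grid=grid,
        missing_prob=missing,
        late_missing_by_class=late_miss,
        post_shift=tuple(post_shift),
        post_noise_sd=tuple(post_noise_sd),
        covariate_model=covariates,
        round_scores=round_scores,
    )


def _draw_mask(rng, config: GeneratorConfig, classes: np.ndarray) -> np.ndarray:
    grid = config.grid
    n = classes.size
    T = grid.n_occasions
    mask = np.ones((n, T), dtype=bool)
    late = {"wk6", "wk8", "wk10", "wk12"}
    late_p = np.asarray(config.late_missing_by_class)[classes]
    for j, lab in enumerate(grid.labels):
        if lab in late:
            p = late_p
        else:
            p = np.full(n, config.missing_prob.get(lab, 0.0))
        mask[:, j] = rng.random(n) >= p
    return mask


def generate(config: GeneratorConfig, seed: Optional[int] = None):
    """Draw one synthetic study sample.

    Returns ``(LongitudinalDataset, GroundTruth)``.  Scores are the latent
    trajectory value plus occasion noise, rounded to integers and truncated
    to [0, 27] (disable via ``config.round_scores``); the missingness mask
    is redrawn per subject until the inclusion rule (screening plus week 2
    or week 4 observed) holds, so every emitted subject is retainable.
    """
    rng = np.random.default_rng(seed)
    grid = config.grid
    lam = build_loading_matrix(grid, config.transformation)
    n, T, K = config.n_subjects, grid.n_occasions, config.n_classes

    classes = rng.choice(K, size=n, p=np.asarray(config.class_proportions))
    mu = np.column_stack(
        [config.intercept_means, config.slope1_means, config.slope2_means]
    )  # (K, 3)
    b = rng.normal(0.0, np.sqrt(config.intercept_var), size=n)
    eta = mu[classes] + np.column_stack([b, np.zeros(n), np.zeros(n)])
    latent = eta @ lam.values.T  # (n, T)
    scores = latent + rng.normal(0.0, np.sqrt(config.residual_var), size=(n, T))

    # outcome: post occasion gets a class shift + extra noise on top of the
    # trajectory endpoint, plus the attitude effect
    cov = config.covariate_model
    apoi_mu = np.asarray(cov["apoi"]["means"])[classes]
    apoi = rng.normal(apoi_mu, cov["apoi"]["sd"])
    j_post = grid.index("post")
    shift = np.asarray(config.post_shift)[classes]
    extra_sd = np.asarray(config.post_noise_sd)[classes]
    scores[:, j_post] = (
        latent[:, j_post]
        + shift
        + rng.normal(0.0, 1.0, size=n) * extra_sd
        + config.apoi_outcome_coef * (apoi - np.mean(cov["apoi"]["means"]))
    )

    raw = scores.copy()
    if config.round_scores:
        scores = np.clip(np.round(scores), 0.0, 27.0)
    else:
        scores = np.clip(scores, 0.0, 27.0)
    trunc_bias = float(np.abs(raw.mean(axis=0) - scores.mean(axis=0)).max())
    logger.info("max per-occasion rounding/truncation bias: %.4f points", trunc_bias)

    # missingness with inclusion-rule redraw
    mask = _draw_mask(rng, config, classes)
    j_scr = grid.index("screening")
    early_idx = [grid.index(l) for l in ("wk2", "wk4") if l in grid.labels]
    for _ in range(100):
        bad = ~(mask[:, j_scr] & mask[:, early_idx].any(axis=1))
        if not bad.any():
            break
        mask[bad] = _draw_mask(rng, config, classes[bad])

    observed = np.where(mask, scores, np.nan)

    # covariates and adherence
    screening_obs = observed[:, j_scr]
    hrsd = cov["hrsd24"]["slope_on_screening"] * latent[:, j_scr] + rng.normal(
        0.0, cov["hrsd24"]["noise_sd"], size=n
    )
    hrsd = np.clip(hrsd, 0.0, 75.0)

    def class_normal(spec):
        return rng.normal(np.asarray(spec["means"])[classes], spec["sd"])

    sf_phys = np.clip(class_normal(cov["sf12_physical"]), 0.0, 100.0)
    sf_ment = np.clip(class_normal(cov["sf12_mental"]), 0.0, 100.0)
    fep2 = np.clip(class_normal(cov["fep2"]), 0.0, 4.0)

    mod_mu = np.asarray([m for m, _ in config.modules_model])[classes]
    mod_sd = np.asarray([s for _, s in config.modules_model])[classes]
    n_modules = np.clip(np.round(rng.normal(mod_mu, mod_sd)), 0.0, None)
    hr_mu = np.asarray([m for m, _ in config.hours_model])[classes]
    hr_sd = np.asarray([s for _, s in config.hours_model])[classes]
    usage_hours = np.clip(rng.normal(hr_mu, hr_sd), 0.0, None)
    late_idx = [grid.index(l) for l in ("wk6", "wk8", "wk10", "wk12") if l in grid.labels]
    n_assessments = mask[:, late_idx].sum(axis=1)

    email_support = (screening_obs >= config.support_threshold).astype(float)

    covariates = pd.DataFrame(
        {
            "hrsd24": hrsd,
            "sf12_physical": sf_phys,
            "sf12_mental": sf_ment,
            "fep2": fep2,
            "apoi": apoi,
            "email_support": email_support,
            "post_phq9": observed[:, j_post],
            "n_modules": n_modules,
            "usage_hours": usage_hours,
            "n_assessments": n_assessments.astype(float),
        }
    )
    ds = LongitudinalDataset(
        subject_ids=[f"s{i + 1:04d}" for i in range(n)],
        grid=grid,
        scores=observed,
        covariates=covariates,
    )
    truth = GroundTruth(classes=classes, growth_factors=eta, latent_scores=latent, raw_scores=raw)
    return ds, truth
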