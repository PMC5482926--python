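"""End-to-end orchestration: simulate/load -> enumerate classes -> classify
reliable change -> association statistics -> report bundle.

The early-change mixture is always fitted on the 4-occasion grid
(screening, registration, week 2, week 4) regardless of how many later
occasions the data carry; downstream statistics use the modal class
assignment from the selected model.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    contingency_analysis,
    hierarchical_regression,
    multinomial_class_prediction,
    oneway_anova_bonferroni,
    screen_predictors,
)
from .data import LongitudinalDataset, read_long_dataset, write_long_dataset
from .grids import build_loading_matrix, default_grid
from .mixture import PiecewiseGrowthMixture
from .reliable_change import (
    DETERIORATED,
    IMPROVED,
    UNCHANGED,
    classify_change_vector,
    compute_rci,
    within_group_effect_size,
)
from .selection import FitSequence, select_n_classes
from .simulate import default_study_config, generate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "read_long_dataset"]

EARLY_LABELS = ("screening", "registration", "wk2", "wk4")


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one of ``data_path`` (with optional ``covariates_path``) or
    ``n_subjects`` (synthetic mode) must be given.
    """

    data_path: Optional[str] = None
    covariates_path: Optional[str] = None
    n_subjects: Optional[int] = None
    k_max: int = 4
    n_bootstrap: int = 99
    alpha: float = 0.05
    reliability: float = 0.86
    baseline_sd: Optional[float] = None  # None: use the sample screening SD
    rci_z: float = 1.96
    n_starts: int = 20
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        synthetic = self.n_subjects is not None
        from_file = self.data_path is not None
        if synthetic == from_file:
            raise ValueError("give exactly one of data_path or n_subjects")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class ReportBundle:
    """Every table of the analysis plus provenance, JSON-serializable."""

    enumeration_table: list
    selection: dict
    fit_summary: dict
    class_summary: list
    outcome_table: dict
    regression: Optional[dict]
    multinomial: Optional[dict]
    predictor_screen: Optional[dict]
    classification: pd.DataFrame
    posterior: pd.DataFrame
    provenance: dict
    notices: list

    def to_json_dict(self) -> dict:
        d = {
            "enumeration_table": self.enumeration_table,
            "selection": self.selection,
            "fit_summary": self.fit_summary,
            "class_summary": self.class_summary,
            "outcome_table": self.outcome_table,
            "regression": self.regression,
            "multinomial": self.multinomial,
            "predictor_screen": self.predictor_screen,
            "provenance": self.provenance,
            "notices": self.notices,
        }
        return _jsonable(d)

    def to_markdown(self) -> str:
        lines = ["# Early-change analysis report", ""]
        lines.append("## Class enumeration")
        lines.append("| K | BIC | SABIC | AIC | Entropy |")
        lines.append("|---|-----|-------|-----|---------|")
        for row in self.enumeration_table:
            ent = "" if row["entropy"] != row["entropy"] else f"{row['entropy']:.2f}"
            lines.append(
                f"| {row['n_classes']} | {row['bic']:.2f} | {row['sabic']:.2f} "
                f"| {row['aic']:.2f} | {ent} |"
            )
        lines.append("")
        lines.append(f"Selected K = {self.selection['chosen_k']} "
                     f"({self.selection['stopping_reason']})")
        lines.append("")
        lines.append("## Classes")
        for row in self.class_summary:
            lines.append(
                f"- class {row['class']}: n={row['n']} ({100 * row['proportion']:.1f}%), "
                f"screening mean {row['screening_mean']:.2f}, "
                f"pre-post d {row['prepost_d']:.2f}, "
                f"reliably improved {row['improved_pct']:.0f}%"
            )
        lines.append("")
        for notice in self.notices:
            lines.append(f"NOTE: {notice}")
        return "\n".join(lines) + "\n"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and obj != obj:
        return None
    return obj


def _load_data(config: RunConfig) -> LongitudinalDataset:
    grid = default_grid()
    if config.data_path is not None:
        return read_long_dataset(config.data_path, grid, covariates_path=config.covariates_path)
    gen = default_study_config(n_subjects=config.n_subjects)
    ds, _ = generate(gen, seed=config.seed)
    return ds.apply_inclusion_filter()


def downstream_statistics(
    ds: LongitudinalDataset,
    labels: np.ndarray,
    reliability: float = 0.86,
    baseline_sd: Optional[float] = None,
    z: float = 1.96,
    class_means: Optional[np.ndarray] = None,
) -> dict:
    """Reliable-change classification and all class-linked statistics.

    ``labels`` are 1-based modal class assignments aligned with ``ds``.
    Returns a dict with the classification table, per-class summary,
    outcome/adherence tables, regression, multinomial fit, predictor
    screen and any notices (e.g. skipped single-class contrasts).
    """
    labels = np.asarray(labels)
    chosen_k = int(labels.max())
    notices: list[str] = []
    pre = ds.column("screening")
    post = ds.column("post")
    sd_screen = baseline_sd if baseline_sd is not None else float(np.nanstd(pre, ddof=1))
    rci = compute_rci(reliability, sd_screen, z=z)
    categories = classify_change_vector(pre, post, rci)
    classification = pd.DataFrame(
        {
            "subject_id": ds.subject_ids,
            "pre": pre,
            "post": post,
            "category": categories,
            "modal_class": labels,
        }
    )

    class_summary = []
    for k in range(chosen_k):
        sel_k = labels == k + 1
        pre_k, post_k = pre[sel_k], post[sel_k]
        ok = ~(np.isnan(pre_k) | np.isnan(post_k))
        d_k = within_group_effect_size(pre_k, post_k, sd_screen) if ok.any() else float("nan")
        n_imp = int(np.sum(categories[sel_k] == IMPROVED))
        n_cls = int(sel_k.sum())
        class_summary.append(
            {
                "class": k + 1,
                "n": n_cls,
                "proportion": n_cls / ds.n_subjects,
                "screening_mean": float(np.nanmean(pre_k)) if n_cls else float("nan"),
                "mean_growth_factors": None
                if class_means is None
                else class_means[k].tolist(),
                "prepost_d": d_k,
                "improved_pct": 100.0 * n_imp / max(n_cls, 1),
            }
        )

    outcome_table: dict = {"rci_threshold": rci.threshold, "baseline_sd": sd_screen}
    regression = multinomial = screen = None
    cov = ds.covariates
    if chosen_k >= 2:
        counts = pd.crosstab(
            pd.Series(labels, name="class"),
            pd.Series(categories, name="category"),
        ).reindex(columns=[IMPROVED, DETERIORATED, UNCHANGED], fill_value=0)
        if (counts.to_numpy().sum(axis=0) > 0).all():
            outcome_table["contingency"] = contingency_analysis(counts).to_dict()
        else:
            notices.append("contingency analysis skipped: empty change category")
        if cov is not None:
            for metric in ("usage_hours", "n_modules", "n_assessments"):
                res = oneway_anova_bonferroni(cov[metric].to_numpy(), labels)
                outcome_table[f"anova_{metric}"] = res.to_dict()
    else:
        notices.append("single-class solution: contingency and ANOVA tables skipped")

    if cov is not None:
        screen_frame = screen_predictors(
            cov[["fep2", "sf12_physical", "sf12_mental", "apoi"]], post
        )
        screen = screen_frame.to_dict(orient="index")
        blocks = [
            ("screening_phq9", pd.DataFrame({"phq9_screening": pre})),
            ("clinician_severity", cov[["hrsd24"]]),
            ("attitudes", cov[["apoi"]]),
            ("support", cov[["email_support"]]),
        ]
        if chosen_k >= 2:
            dummies = pd.get_dummies(pd.Series(labels, name="class"), prefix="class").iloc[:, 1:]
            blocks.append(("class_membership", dummies.astype(float)))
        ok = ~np.isnan(post)
        blocks_ok = [(nm, bl.loc[ok].reset_index(drop=True)) for nm, bl in blocks]
        regression = hierarchical_regression(post[ok], blocks_ok).to_dict()
        if chosen_k >= 2:
            design = cov[
                ["hrsd24", "fep2", "sf12_physical", "sf12_mental", "email_support"]
            ].copy()
            design.insert(0, "phq9_screening", pre)
            multinomial = multinomial_class_prediction(design, labels, reference_class=1).to_dict()
        else:
            notices.append("single-class solution: multinomial prediction skipped")

    return {
        "classification": classification,
        "class_summary": class_summary,
        "outcome_table": outcome_table,
        "regression": regression,
        "multinomial": multinomial,
        "predictor_screen": screen,
        "notices": notices,
    }


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``.

    Stages: load or simulate data; fit mixtures for K = 1..k_max on the
    early-change grid and select K by the two-fold BIC/BLRT rule; assign
    modal classes; classify reliable pre-post change; compute the
    association statistics.  All randomness derives from ``config.seed``.
    """
    notices: list[str] = []
    ds = _load_data(config)
    early = ds.restrict_occasions(list(EARLY_LABELS))
    lam = build_loading_matrix(early.grid)
    rng = np.random.default_rng(config.seed)
    fit_seed, blrt_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))

    if config.k_max < 2:
        model = PiecewiseGrowthMixture(
            n_classes=1, loading_matrix=lam, n_starts=config.n_starts, random_state=fit_seed
        ).fit(early.scores)
        seq = FitSequence(fits={1: model}, converged={1: model.converged_})
        selection = {
            "chosen_k": 1,
            "bic_path": [model.bic_],
            "blrt_trail": [],
            "stopping_reason": "k_max=1: single-class model by configuration",
        }
        blrt_results = []
        notices.append("k_max=1: class-contrast statistics skipped")
    else:
        sel, seq, blrt_results = select_n_classes(
            early.scores,
            k_max=config.k_max,
            n_bootstrap=config.n_bootstrap,
            alpha=config.alpha,
            seed=config.seed,
            loading_matrix=lam,
            n_starts=config.n_starts,
        )
        selection = sel.to_dict()

    chosen_k = selection["chosen_k"]
    best = seq.fits[chosen_k]
    labels = best.labels_ + 1  # report classes as 1-based
    posterior = pd.DataFrame(
        best.posterior_,
        columns=[f"p_class{k + 1}" for k in range(chosen_k)],
    )
    posterior.insert(0, "subject_id", ds.subject_ids)
    posterior["modal_class"] = labels

    down = downstream_statistics(
        ds,
        labels,
        reliability=config.reliability,
        baseline_sd=config.baseline_sd,
        z=config.rci_z,
        class_means=best.means_,
    )
    notices.extend(down["notices"])
    classification = down["classification"]
    class_summary = down["class_summary"]
    outcome_table = down["outcome_table"]
    regression = down["regression"]
    multinomial = down["multinomial"]
    screen = down["predictor_screen"]

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "derived_seeds": {"fit": fit_seed, "blrt": blrt_seed},
        "config": config.to_dict(),
        "config_hash": hashlib.md5(
            json.dumps(_jsonable(config.to_dict()), sort_keys=True).encode()
        ).hexdigest(),
        "n_subjects": ds.n_subjects,
        "blrt": [b.to_dict() | {"bootstrap_statistics": None} for b in blrt_results],
    }

    bundle = ReportBundle(
        enumeration_table=seq.table(),
        selection=selection,
        fit_summary=best.fit_summary(seed=config.seed).to_dict(),
        class_summary=class_summary,
        outcome_table=outcome_table,
        regression=regression,
        multinomial=multinomial,
        predictor_screen=screen,
        classification=classification,
        posterior=posterior,
        provenance=provenance,
        notices=notices,
    )
    if config.out_dir is not None:
        _write_bundle(bundle, ds, Path(config.out_dir))
    return bundle


def _write_bundle(bundle: ReportBundle, ds: LongitudinalDataset, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_long_dataset(ds, out / "data_long.tsv", out / "covariates.tsv")
    bundle.posterior.to_csv(out / "posterior.tsv", sep="\t", index=False)
    bundle.classification.to_csv(out / "classification.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(bundle.to_json_dict(), fh, indent=2)
    with open(out / "report.md", "w") as fh:
        fh.write(bundle.to_markdown())
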