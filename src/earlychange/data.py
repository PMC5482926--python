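"""Longitudinal dataset container and delimited-text I/O.

Scores live in a subject x occasion matrix with NaN marking missing
assessments; covariates are a per-subject table aligned by subject id.
The inclusion rule of the study design — a non-missing screening score and
at least one observed assessment at week 2 or week 4 — is applied at load
time, with the number of excluded subjects logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grids import OccasionGrid

logger = logging.getLogger(__name__)

__all__ = ["LongitudinalDataset", "read_long_dataset", "write_long_dataset"]

SCORE_MIN, SCORE_MAX = 0.0, 27.0
EARLY_OCCASIONS = ("wk2", "wk4")


@dataclass
class LongitudinalDataset:
    """Per-subject score series on a labelled occasion grid plus covariates.

    Attributes
    ----------
    subject_ids : list
        Subject identifiers, aligned with the rows of ``scores``.
    grid : OccasionGrid
        The occasion grid the columns of ``scores`` follow.
    scores : ndarray of shape (n_subjects, n_occasions)
        Observed scores; NaN where the assessment is missing.
    covariates : DataFrame or None
        Per-subject covariate table indexed like ``subject_ids``.
    """

    subject_ids: list
    grid: OccasionGrid
    scores: np.ndarray
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != self.grid.n_occasions:
            raise ValueError("scores must be n_subjects x n_occasions")
        if len(self.subject_ids) != self.scores.shape[0]:
            raise ValueError("subject_ids must align with score rows")
        obs = self.scores[~np.isnan(self.scores)]
        if obs.size and (obs.min() < SCORE_MIN or obs.max() > SCORE_MAX):
            raise ValueError(f"scores must lie in [{SCORE_MIN:g}, {SCORE_MAX:g}]")
        if self.covariates is not None and len(self.covariates) != len(self.subject_ids):
            raise ValueError("covariate table must have one row per subject")

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Boolean observed-mask, True where a score was recorded."""
        return ~np.isnan(self.scores)

    def column(self, label: str) -> np.ndarray:
        return self.scores[:, self.grid.index(label)]

    def meets_inclusion(self) -> np.ndarray:
        """Inclusion rule: screening observed and wk2 or wk4 observed."""
        ok = ~np.isnan(self.column("screening"))
        early = np.zeros(self.n_subjects, dtype=bool)
        for lab in EARLY_OCCASIONS:
            if lab in self.grid.labels:
                early |= ~np.isnan(self.column(lab))
        return ok & early

    def apply_inclusion_filter(self) -> "LongitudinalDataset":
        """Drop subjects failing the inclusion rule (count is logged)."""
        keep = self.meets_inclusion()
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("inclusion filter removed %d of %d subjects", n_drop, self.n_subjects)
        return self.subset(np.flatnonzero(keep))

    def subset(self, rows: Sequence[int]) -> "LongitudinalDataset":
        rows = np.asarray(rows, dtype=int)
        cov = self.covariates.iloc[rows].reset_index(drop=True) if self.covariates is not None else None
        return LongitudinalDataset(
            subject_ids=[self.subject_ids[i] for i in rows],
            grid=self.grid,
            scores=self.scores[rows],
            covariates=cov,
        )

    def restrict_occasions(self, labels: Sequence[str]) -> "LongitudinalDataset":
        """Dataset restricted to a subset of occasions (e.g. the early grid)."""
        sub = self.grid.subset(labels)
        idx = [self.grid.index(l) for l in labels]
        return LongitudinalDataset(
            subject_ids=list(self.subject_ids),
            grid=sub,
            scores=self.scores[:, idx],
            covariates=self.covariates,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (subject_id, occasion, score) frame of observed rows."""
        recs = []
        for i, sid in enumerate(self.subject_ids):
            for j, lab in enumerate(self.grid.labels):
                v = self.scores[i, j]
                if not np.isnan(v):
                    recs.append((sid, lab, v))
        return pd.DataFrame(recs, columns=["subject_id", "occasion", "score"])


def read_long_dataset(
    path,
    grid: OccasionGrid,
    covariates_path=None,
    apply_inclusion: bool = True,
    sep: str = "\t",
) -> LongitudinalDataset:
    """Read a long-format delimited file into a :class:`LongitudinalDataset`.

    The file needs columns ``subject_id``, ``occasion`` and ``score``.
    Unknown occasion labels, duplicate (subject, occasion) pairs and
    out-of-range scores are rejected with the offending row named.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"subject_id", "occasion", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"long file must have columns {sorted(required)}")
    unknown = set(df["occasion"]) - set(grid.labels)
    if unknown:
        rows = df.index[df["occasion"].isin(unknown)].tolist()
        raise ValueError(f"unknown occasion labels {sorted(unknown)} (rows {rows[:5]})")
    dup = df.duplicated(subset=["subject_id", "occasion"])
    if dup.any():
        raise ValueError(f"duplicate (subject, occasion) rows: {df.index[dup].tolist()[:5]}")
    bad = (df["score"] < SCORE_MIN) | (df["score"] > SCORE_MAX)
    if bad.any():
        i = int(df.index[bad][0])
        raise ValueError(f"score {df.loc[i, 'score']} out of range at row {i}")

    subjects = list(pd.unique(df["subject_id"]))
    scores = np.full((len(subjects), grid.n_occasions), np.nan)
    sidx = {s: i for i, s in enumerate(subjects)}
    for _, row in df.iterrows():
        scores[sidx[row["subject_id"]], grid.index(row["occasion"])] = row["score"]

    cov = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, sep=sep)
        if "subject_id" not in cov.columns:
            raise ValueError("covariate table must have a subject_id column")
        cov = cov.set_index("subject_id").reindex(subjects).reset_index()

    ds = LongitudinalDataset(subject_ids=subjects, grid=grid, scores=scores, covariates=cov)
    return ds.apply_inclusion_filter() if apply_inclusion else ds


def write_long_dataset(ds: LongitudinalDataset, path, covariates_path=None, sep: str = "\t") -> None:
    """Write ``ds`` as long-format delimited text (plus optional covariates)."""
    ds.to_long_frame().to_csv(path, sep=sep, index=False)
    if covariates_path is not None and ds.covariates is not None:
        out = ds.covariates.copy()
        if "subject_id" not in out.columns:
            out.insert(0, "subject_id", ds.subject_ids)
        out.to_csv(covariates_path, sep=sep, index=False)
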