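"""Occasion grids and piecewise growth-factor loading matrices.

A trajectory is summarised by three latent growth factors: an intercept
(initial severity), a first slope for the pre-treatment phase (screening to
registration) and a second slope for the early-intervention phase
(registration through week 4 and beyond).  The loading matrix fixes how each
occasion weights those factors: the intercept loads 1 everywhere, the first
slope loads 0 at screening and 1 thereafter, and the second slope loads 0 on
the first two occasions and a (log-linear by default) transform of the
occasion's time index afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "OccasionGrid",
    "LoadingMatrix",
    "build_loading_matrix",
    "default_grid",
    "early_change_grid",
]

#: Default occasion labels of the 12-week design: a screening assessment,
#: a registration assessment, biweekly assessments during the intervention
#: and a post-treatment assessment.
DEFAULT_LABELS = (
    "screening",
    "registration",
    "wk2",
    "wk4",
    "wk6",
    "wk8",
    "wk10",
    "wk12",
    "post",
)


@dataclass(frozen=True)
class OccasionGrid:
    """Ordered assessment occasions with their piecewise time codes.

    Parameters
    ----------
    labels : sequence of str
        Unique occasion names in temporal order.
    phase1_indicator : sequence of int
        0 at the first occasion (screening), 1 at every later occasion.
    phase2_time : sequence of float
        0 on the first two occasions, then a strictly increasing positive
        time index (2 at the first biweekly assessment, 3 at the next, ...).
    """

    labels: tuple[str, ...]
    phase1_indicator: tuple[int, ...]
    phase2_time: tuple[float, ...]

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        p1 = tuple(int(v) for v in self.phase1_indicator)
        p2 = tuple(float(v) for v in self.phase2_time)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "phase1_indicator", p1)
        object.__setattr__(self, "phase2_time", p2)
        if len(labels) < 2:
            raise ValueError("an occasion grid needs at least 2 occasions")
        if len(set(labels)) != len(labels):
            raise ValueError("occasion labels must be unique")
        if not (len(labels) == len(p1) == len(p2)):
            raise ValueError("labels, phase1_indicator and phase2_time must align")
        if p1[0] != 0 or any(v != 1 for v in p1[1:]):
            raise ValueError("phase1_indicator must be 0 at the first occasion and 1 after")
        if p2[0] != 0.0 or p2[1] != 0.0:
            raise ValueError("phase2_time must be 0 on the first two occasions")
        tail = p2[2:]
        if any(t <= 0 for t in tail) or any(b <= a for a, b in zip(tail, tail[1:])):
            raise ValueError("phase2_time must be positive and strictly increasing after registration")

    @property
    def n_occasions(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels: Sequence[str]) -> "OccasionGrid":
        """Grid restricted to ``labels`` (kept in grid order)."""
        idx = [self.index(l) for l in labels]
        if idx != sorted(idx):
            raise ValueError("subset labels must respect grid order")
        return OccasionGrid(
            tuple(self.labels[i] for i in idx),
            tuple(self.phase1_indicator[i] for i in idx),
            tuple(self.phase2_time[i] for i in idx),
        )


@dataclass(frozen=True)
class LoadingMatrix:
    """T x 3 fixed factor-loading matrix (intercept, slope1, slope2)."""

    values: np.ndarray
    labels: tuple[str, ...]
    transformation: str = "log_linear"
    column_roles: tuple[str, str, str] = ("intercept", "slope1", "slope2")

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))
        if vals.ndim != 2 or vals.shape[1] != 3:
            raise ValueError("loading matrix must be T x 3")
        if vals.shape[0] != len(self.labels):
            raise ValueError("row count must match occasion labels")
        if not np.all(vals[:, 0] == 1.0):
            raise ValueError("intercept loadings must all equal 1")

    @property
    def n_occasions(self) -> int:
        return self.values.shape[0]


def build_loading_matrix(grid: OccasionGrid, transformation: str = "log_linear") -> LoadingMatrix:
    """Build the fixed piecewise loading matrix for ``grid``.

    ``transformation`` selects the second-slope time coding: ``"log_linear"``
    applies log base 10 to the positive phase-2 time indices (so the biweekly
    assessments at indices 2 and 3 load 0.30103 and 0.47712), ``"linear"``
    uses them untransformed.
    """
    if transformation not in ("log_linear", "linear"):
        raise ValueError(f"unknown transformation {transformation!r}")
    t2 = np.asarray(grid.phase2_time, dtype=float)
    slope2 = np.zeros_like(t2)
    pos = t2 > 0
    slope2[pos] = np.log10(t2[pos]) if transformation == "log_linear" else t2[pos]
    values = np.column_stack(
        [np.ones(grid.n_occasions), np.asarray(grid.phase1_indicator, dtype=float), slope2]
    )
    return LoadingMatrix(values=values, labels=grid.labels, transformation=transformation)


def default_grid() -> OccasionGrid:
    """Full study grid: screening, registration, biweekly wk2..wk12, post."""
    # time index 2 at wk2, 3 at wk4, ..., 8 at post (biweekly steps)
    return OccasionGrid(
        labels=DEFAULT_LABELS,
        phase1_indicator=(0,) + (1,) * 8,
        phase2_time=(0.0, 0.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0),
    )


def early_change_grid() -> OccasionGrid:
    """The 4-occasion grid the early-change model is fitted on."""
    return default_grid().subset(["screening", "registration", "wk2", "wk4"])
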