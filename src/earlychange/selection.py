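"""Latent-class enumeration: BIC path plus bootstrapped likelihood ratio test.

The decision procedure is two-fold.  Models with 1, 2, ... classes are
fitted until the BIC no longer decreases; the candidate solution (the last
K before the increase) is then tested against the (K-1)-class solution
with a parametric-bootstrap likelihood ratio test (BLRT).  If the BLRT is
significant the candidate is kept; otherwise the procedure steps down —
K-1 against K-2, and so on — until a significant test is found, falling
back to a single class if none is.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Optional, Sequence

import numpy as np

from .mixture import ConvergenceError, PiecewiseGrowthMixture

__all__ = [
    "FitSequence",
    "BLRTResult",
    "SelectionResult",
    "fit_sequence",
    "blrt",
    "bootstrap_p",
    "select_by_bic_blrt",
    "select_n_classes",
]


@dataclass
class FitSequence:
    """Fits for K = 1..K_max on one dataset with one loading matrix."""

    fits: dict  # K -> fitted PiecewiseGrowthMixture
    converged: dict  # K -> bool

    @property
    def k_values(self) -> list[int]:
        return sorted(self.fits)

    @property
    def bic_path(self) -> list[float]:
        return [self.fits[k].bic_ for k in self.k_values]

    def table(self) -> list[dict]:
        """One row per K: information criteria and entropy."""
        rows = []
        for k in self.k_values:
            f = self.fits[k]
            rows.append(
                {
                    "n_classes": k,
                    "bic": f.bic_,
                    "sabic": f.sabic_,
                    "aic": f.aic_,
                    "entropy": f.entropy_,
                    "log_likelihood": f.log_likelihood_,
                    "converged": self.converged[k],
                }
            )
        return rows


@dataclass
class BLRTResult:
    """Parametric-bootstrap likelihood ratio test of K vs K-1 classes."""

    k: int
    observed_statistic: float
    bootstrap_statistics: list
    n_bootstrap: int
    p_value: float
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SelectionResult:
    """Chosen class count with the full decision trail."""

    chosen_k: int
    bic_path: list
    blrt_trail: list  # [(k, p_value), ...] in testing order
    stopping_reason: str

    def to_dict(self) -> dict:
        return asdict(self)


def _derive_seeds(seed: Optional[int], n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def bootstrap_p(replicate_statistics: Sequence[float], observed: float) -> float:
    """p = (1 + #{replicates >= observed}) / (B + 1); order-invariant."""
    stats = list(replicate_statistics)
    n_ge = sum(1 for s in stats if s >= observed)
    return (1.0 + n_ge) / (len(stats) + 1.0)


def fit_sequence(
    data,
    k_max: int,
    seed: Optional[int] = None,
    loading_matrix=None,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> FitSequence:
    """Fit best-of-starts mixtures for K = 1..k_max.

    Per-K seeds are derived deterministically from the master seed, so the
    sequence is reproducible as a whole.  A K whose every start collapses
    is flagged unconverged and the sequence continues.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    seeds = _derive_seeds(seed, k_max)
    fits, conv = {}, {}
    for k in range(1, k_max + 1):
        model = PiecewiseGrowthMixture(
            n_classes=k,
            loading_matrix=loading_matrix,
            n_starts=n_starts,
            max_iter=max_iter,
            tol=tol,
            random_state=seeds[k - 1],
        )
        try:
            model.fit(data)
            fits[k] = model
            conv[k] = model.converged_
        except ConvergenceError:
            conv[k] = False
    if not fits:
        raise ConvergenceError("no class count admitted a converged fit")
    return FitSequence(fits=fits, converged=conv)


def blrt(
    data,
    k: int,
    n_bootstrap: int = 99,
    seed: Optional[int] = None,
    loading_matrix=None,
    fit_null: Optional[PiecewiseGrowthMixture] = None,
    fit_alt: Optional[PiecewiseGrowthMixture] = None,
    n_starts: int = 20,
    replicate_starts: int = 4,
    replicate_max_iter: int = 100,
) -> BLRTResult:
    """Bootstrapped likelihood ratio test of ``k`` vs ``k - 1`` classes.

    The null distribution of -2 (LL_{k-1} - LL_k) is simulated by drawing
    ``n_bootstrap`` datasets from the fitted (k-1)-class model — with the
    parent data's missingness mask reapplied verbatim — and refitting both
    models on each.  Replicate refits warm-start from the parent fit's
    parameters plus ``replicate_starts`` random starts.  A replicate whose
    refit degenerates is redrawn up to 3 times and then counted
    conservatively as exceeding the observed statistic.

    p = (1 + #{replicate statistics >= observed}) / (n_bootstrap + 1).
    """
    if k < 2:
        raise ValueError("the BLRT compares k >= 2 against k - 1")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    X = PiecewiseGrowthMixture._coerce(data)
    mask = ~np.isnan(X)
    n = X.shape[0]
    seeds = _derive_seeds(seed, 2 + 9 * n_bootstrap)
    si = iter(seeds)

    def full_fit(n_classes, seed_):
        m = PiecewiseGrowthMixture(
            n_classes=n_classes,
            loading_matrix=loading_matrix,
            n_starts=n_starts,
            random_state=seed_,
        )
        return m.fit(X)

    if fit_null is None:
        fit_null = full_fit(k - 1, next(si))
    else:
        next(si)
    if fit_alt is None:
        fit_alt = full_fit(k, next(si))
    else:
        next(si)
    observed = -2.0 * (fit_null.log_likelihood_ - fit_alt.log_likelihood_)

    def refit(n_classes, parent, Xb, seed_):
        m = PiecewiseGrowthMixture(
            n_classes=n_classes,
            loading_matrix=loading_matrix,
            n_starts=replicate_starts,
            max_iter=replicate_max_iter,
            random_state=seed_,
        )
        init = (parent.weights_, parent.means_, parent.intercept_var_, parent.residual_var_)
        return m.fit(Xb, init_params=init)

    stats = []
    n_conservative = 0
    for _ in range(n_bootstrap):
        stat = None
        for _attempt in range(3):
            Xb, _ = fit_null.sample(n, random_state=next(si), mask=mask)
            try:
                m0 = refit(k - 1, fit_null, Xb, next(si))
                m1 = refit(k, fit_alt, Xb, next(si))
            except ConvergenceError:
                continue
            stat = -2.0 * (m0.log_likelihood_ - m1.log_likelihood_)
            break
        if stat is None:
            stat = float("inf")  # conservative: counts as >= observed
            n_conservative += 1
        stats.append(float(stat))

    p = bootstrap_p(stats, observed)
    return BLRTResult(
        k=k,
        observed_statistic=float(observed),
        bootstrap_statistics=stats,
        n_bootstrap=n_bootstrap,
        p_value=float(p),
        seed=seed,
    )


def select_by_bic_blrt(
    bic_path: Sequence[float],
    blrt_runner: Callable[[int], float],
    alpha: float = 0.05,
) -> SelectionResult:
    """Apply the two-fold enumeration rule to a BIC path.

    ``bic_path[i]`` is the BIC of the (i+1)-class model.  The candidate is
    the first K at which the BIC stops decreasing (BIC(K+1) >= BIC(K), ties
    included), or K_max if it decreases throughout.  ``blrt_runner(k)``
    must return the BLRT p-value of k vs k-1; it is called only as the
    step-down loop requires.  Falls back to K = 1 if every test is
    non-significant.
    """
    bic_path = [float(b) for b in bic_path]
    k_max = len(bic_path)
    if k_max < 1:
        raise ValueError("bic_path must be non-empty")
    candidate = k_max
    for k in range(1, k_max):
        if bic_path[k] >= bic_path[k - 1]:
            candidate = k
            break
    trail = []
    k = candidate
    while k >= 2:
        p = float(blrt_runner(k))
        trail.append((k, p))
        if p < alpha:
            return SelectionResult(
                chosen_k=k,
                bic_path=bic_path,
                blrt_trail=trail,
                stopping_reason=f"BLRT({k} vs {k - 1}) significant at alpha={alpha}",
            )
        k -= 1
    reason = (
        "BIC increased from K=1; no BLRT invoked"
        if candidate == 1
        else "no significant BLRT; fell back to a single class"
    )
    return SelectionResult(chosen_k=1, bic_path=bic_path, blrt_trail=trail, stopping_reason=reason)


def select_n_classes(
    data,
    k_max: int = 4,
    n_bootstrap: int = 99,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    loading_matrix=None,
    n_starts: int = 20,
) -> tuple[SelectionResult, FitSequence, list[BLRTResult]]:
    """End-to-end enumeration: fit K = 1..k_max, then apply the two-fold rule."""
    seq_seed, blrt_seed = _derive_seeds(seed, 2)
    seq = fit_sequence(
        data, k_max, seed=seq_seed, loading_matrix=loading_matrix, n_starts=n_starts
    )
    blrt_results: list[BLRTResult] = []
    blrt_seeds = _derive_seeds(blrt_seed, k_max + 1)

    def runner(k: int) -> float:
        res = blrt(
            data,
            k,
            n_bootstrap=n_bootstrap,
            seed=blrt_seeds[k],
            loading_matrix=loading_matrix,
            fit_null=seq.fits.get(k - 1),
            fit_alt=seq.fits.get(k),
            n_starts=n_starts,
        )
        blrt_results.append(res)
        return res.p_value

    if 1.0 / (n_bootstrap + 1.0) >= alpha:
        import logging

        logging.getLogger(__name__).warning(
            "n_bootstrap=%d cannot reach p < %g (min attainable p = %g); "
            "every BLRT will be non-significant",
            n_bootstrap,
            alpha,
            1.0 / (n_bootstrap + 1.0),
        )
    sel = select_by_bic_blrt(seq.bic_path, runner, alpha=alpha)
    return sel, seq, blrt_results
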