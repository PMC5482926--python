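"""Piecewise growth mixture model (PGMM) with EM estimation.

The model: subject ``i`` in latent class ``k`` has growth factors
``eta_i = mu_k + (b_i, 0, 0)`` — a class mean vector (intercept, phase-1
slope, phase-2 slope) plus a subject-specific intercept deviation
``b_i ~ N(0, psi)`` — and observed scores ``y_it = Lambda_t eta_i + e_it``
with ``e_it ~ N(0, theta)``.  Slope variances are fixed to zero, the
intercept variance ``psi`` is free but shared across classes, and a single
residual variance ``theta`` is shared across occasions and classes, so all
heterogeneity in *change* is carried by the class mean slopes.

Because the intercept loading is 1 at every occasion, the within-class
covariance of a subject's observed sub-vector is compound symmetric,
``psi * J + theta * I``, which the implementation exploits throughout
(Sherman–Morrison inverse, closed-form determinant).  Subjects with
partially missing series contribute through the marginal normal density of
their observed coordinates only (full-information likelihood); no
imputation is performed.

Estimation is EM over (class membership, intercept deviation) with a
conditional M-step: class means are updated by weighted least squares
first, then the two variance components given the new means.  Both updates
are closed form and the observed-data log-likelihood is non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .data import LongitudinalDataset
from .grids import LoadingMatrix, build_loading_matrix, early_change_grid

logger = logging.getLogger(__name__)

__all__ = [
    "PiecewiseGrowthMixture",
    "PGMMFit",
    "ConvergenceError",
    "em_fit",
    "marginal_loglik_subject",
    "information_criteria",
    "relative_entropy",
    "classify_subjects",
]

_LOG_2PI = np.log(2.0 * np.pi)
_PSI_FLOOR = 1e-10
_THETA_FLOOR = 1e-8


class ConvergenceError(RuntimeError):
    """Raised when no EM start yields an admissible converged solution."""


def information_criteria(loglik: float, p: int, n: int) -> tuple[float, float, float]:
    """Return (BIC, SABIC, AIC).

    BIC = -2 LL + p ln n; the sample-size-adjusted BIC replaces ln n with
    ln((n + 2) / 24); AIC = -2 LL + 2 p.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bic = -2.0 * loglik + p * np.log(n)
    sabic = -2.0 * loglik + p * np.log((n + 2.0) / 24.0)
    aic = -2.0 * loglik + 2.0 * p
    return float(bic), float(sabic), float(aic)


def relative_entropy(posterior: np.ndarray, n_classes: Optional[int] = None) -> float:
    """Relative entropy of a posterior matrix, in [0, 1].

    1 - sum_i sum_k (-p_ik ln p_ik) / (n ln K): 1 for fully certain (0/1)
    posteriors, 0 for uniform ones.  Undefined for a single class
    (returns NaN).
    """
    post = np.asarray(posterior, dtype=float)
    K = n_classes if n_classes is not None else post.shape[1]
    if K < 2:
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(post > 0, -post * np.log(post), 0.0)
    n = post.shape[0]
    return float(1.0 - terms.sum() / (n * np.log(K)))


def marginal_loglik_subject(
    observed_scores: np.ndarray,
    mask: np.ndarray,
    mu_k: np.ndarray,
    psi: float,
    theta: float,
    lam: np.ndarray | LoadingMatrix,
) -> float:
    """Log-density of one subject's observed scores under class ``k``.

    The observed sub-vector is multivariate normal with mean
    ``(Lambda mu_k)`` restricted to observed rows and covariance
    ``psi * J + theta * I`` on those rows.
    """
    if theta <= 0:
        raise ValueError("residual variance theta must be positive")
    if psi < 0:
        raise ValueError("intercept variance psi must be non-negative")
    L = lam.values if isinstance(lam, LoadingMatrix) else np.asarray(lam, dtype=float)
    y = np.asarray(observed_scores, dtype=float)
    w = np.asarray(mask, dtype=bool)
    if not w.any():
        raise ValueError("subject has no observed coordinates")
    mean = L @ np.asarray(mu_k, dtype=float)
    r = y[w] - mean[w]
    n_obs = int(w.sum())
    denom = theta + n_obs * psi
    logdet = (n_obs - 1) * np.log(theta) + np.log(denom)
    quad = (np.sum(r * r) - psi * np.sum(r) ** 2 / denom) / theta
    return float(-0.5 * (n_obs * _LOG_2PI + logdet + quad))


def classify_subjects(posterior: np.ndarray) -> np.ndarray:
    """Modal class per subject; ties break toward the lower class index."""
    return np.argmax(np.asarray(posterior, dtype=float), axis=1)


@dataclass
class PGMMFit:
    """Serializable summary of a fitted piecewise growth mixture."""

    n_classes: int
    weights: list
    means: list
    intercept_var: float
    residual_var: float
    log_likelihood: float
    n_parameters: int
    n_subjects: int
    bic: float
    sabic: float
    aic: float
    entropy: float
    n_iter: int
    best_start: int
    converged: bool
    seed: Optional[int]

    def to_dict(self) -> dict:
        return asdict(self)


class PiecewiseGrowthMixture(BaseEstimator):
    """Mixture of piecewise latent growth curves with fixed loadings.

    Parameters
    ----------
    n_classes : int, default=3
        Number of latent trajectory classes (K >= 1).
    loading_matrix : LoadingMatrix or None
        Fixed T x 3 loadings; defaults to the log-linear early-change
        loadings on (screening, registration, wk2, wk4).
    n_starts : int, default=20
        Random EM starts (perturbations of a k-means partition); the best
        final log-likelihood wins.
    max_iter : int, default=500
        EM iteration cap per start.
    tol : float, default=1e-7
        Relative log-likelihood change declaring convergence.
    random_state : int or None
        Seed for start generation; identical seeds give identical fits.

    Attributes
    ----------
    weights_ : ndarray (K,)          mixing proportions
    means_ : ndarray (K, 3)          class mean growth factors
    intercept_var_ : float           shared intercept variance psi
    residual_var_ : float            shared residual variance theta
    log_likelihood_ : float          observed-data log-likelihood
    n_parameters_ : int              (K - 1) + 3 K + 2
    bic_, sabic_, aic_ : float       information criteria
    entropy_ : float                 relative entropy (NaN for K = 1)
    posterior_ : ndarray (n, K)      class membership probabilities
    labels_ : ndarray (n,)           modal class assignment
    """

    def __init__(
        self,
        n_classes: int = 3,
        loading_matrix: Optional[LoadingMatrix] = None,
        n_starts: int = 20,
        max_iter: int = 500,
        tol: float = 1e-7,
        random_state: Optional[int] = None,
    ):
        self.n_classes = n_classes
        self.loading_matrix = loading_matrix
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _lam(self) -> LoadingMatrix:
        if self.loading_matrix is not None:
            return self.loading_matrix
        return build_loading_matrix(early_change_grid())

    @staticmethod
    def _coerce(X) -> np.ndarray:
        if isinstance(X, LongitudinalDataset):
            return X.scores
        return np.asarray(X, dtype=float)

    def _validate(self, X) -> np.ndarray:
        X = self._coerce(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (subjects x occasions)")
        lam = self._lam()
        if X.shape[1] != lam.n_occasions:
            raise ValueError(
                f"X has {X.shape[1]} occasions but the loading matrix has {lam.n_occasions}"
            )
        if np.isnan(X).all(axis=1).any():
            raise ValueError("every subject needs at least one observed occasion")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if X.shape[0] < 3 * self.n_classes:
            raise ValueError("too few subjects for the requested number of classes")
        return X

    # -- likelihood machinery ------------------------------------------
    def _stats(self, W, WY, sWY, sY2, means):
        """Per-subject, per-class residual sums for the compound-symmetric
        marginal: S1 = sum of residuals, S2 = sum of squared residuals.
        Independent of the variance components, so reusable across the
        E-step and the variance update."""
        M = means @ self._L.T  # (K, T) class mean curves
        MM = np.concatenate([M, M * M], axis=0)  # one matmul for both
        WMM = W @ MM.T  # (n, 2K)
        K = M.shape[0]
        S1 = sWY[:, None] - WMM[:, :K]
        S2 = sY2[:, None] - 2.0 * (WY @ M.T) + WMM[:, K:]
        return S1, S2

    @staticmethod
    def _log_density_from_stats(S1, S2, n_obs, weights, psi, theta):
        denom = theta + n_obs[:, None] * psi
        logdet = (n_obs - 1)[:, None] * np.log(theta) + np.log(denom)
        quad = (S2 - psi * S1 * S1 / denom) / theta
        logf = -0.5 * (n_obs[:, None] * _LOG_2PI + logdet + quad)
        return logf + np.log(weights)[None, :], denom

    def _em_run(self, Y0, W, sY2, n_obs, weights, means, psi, theta):
        """One EM run from the given parameters; returns final state."""
        n, K = Y0.shape[0], self.n_classes
        floor = 1.0 / (2.0 * n)
        WY = Y0 * W
        sWY = WY.sum(axis=1)
        N_obs = n_obs.sum()
        L = self._L
        ll_prev = -np.inf
        ll = -np.inf
        trace = []
        S1, S2 = self._stats(W, WY, sWY, sY2, means)
        for it in range(1, self.max_iter + 1):
            logw, denom = self._log_density_from_stats(S1, S2, n_obs, weights, psi, theta)
            mx = logw.max(axis=1, keepdims=True)
            P = np.exp(logw - mx)
            sP = P.sum(axis=1, keepdims=True)
            ll = float((np.log(sP) + mx).sum())
            trace.append(ll)
            P /= sP

            weights = P.mean(axis=0)
            if K > 1 and weights.min() < floor:
                return None  # degenerate class: discard this start
            # intercept-deviation posterior moments (old means)
            m = psi * S1 / denom  # (n, K)
            v = psi * theta / denom[:, 0]  # (n,)
            # class mean curves by weighted least squares, batched over k
            WK = P.T @ W  # (K, T)
            c = (P.T @ WY - (P * m).T @ W) @ L  # (K, 3)
            A = np.einsum("kt,ti,tj->kij", WK, L, L)
            means = np.linalg.solve(A, c[:, :, None])[:, :, 0]
            # variance components given the new means
            S1, S2 = self._stats(W, WY, sWY, sY2, means)
            rss = (P * (S2 - 2.0 * m * S1 + n_obs[:, None] * m * m)).sum()
            theta = max((rss + (n_obs * v).sum()) / N_obs, _THETA_FLOOR)
            psi = max(((P * m * m).sum() + v.sum()) / n, _PSI_FLOOR)

            if ll - ll_prev < self.tol * max(1.0, abs(ll)) and it > 1:
                converged = True
                break
            ll_prev = ll
        else:
            converged = False
        # final log-likelihood at the returned (post-update) parameters
        logw, _ = self._log_density_from_stats(S1, S2, n_obs, weights, psi, theta)
        ll = float(logsumexp(logw, axis=1).sum())
        trace.append(ll)
        return weights, means, psi, theta, ll, it, converged, trace

    # -- initialisation -------------------------------------------------
    def _kmeans_partition(self, X, rng) -> np.ndarray:
        """Partition subjects on (first-occasion, last-observed) pairs."""
        first = X[:, 0]
        last = np.full(X.shape[0], np.nan)
        for j in range(X.shape[1] - 1, -1, -1):
            fill = np.isnan(last) & ~np.isnan(X[:, j])
            last[fill] = X[fill, j]
        feats = np.column_stack([first, last])
        col_mean = np.nanmean(feats, axis=0)
        feats = np.where(np.isnan(feats), col_mean, feats)
        km = KMeans(
            n_clusters=self.n_classes,
            n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        return km.fit_predict(feats)

    def _init_from_partition(self, Y0, W, sY2, n_obs, labels):
        n, K = Y0.shape[0], self.n_classes
        weights = np.bincount(labels, minlength=K).astype(float)
        weights = np.maximum(weights, 1.0)
        weights /= weights.sum()
        means = np.zeros((K, 3))
        for k in range(K):
            rows = labels == k
            if rows.sum() == 0:
                rows = np.ones(n, dtype=bool)
            wk = W[rows].sum(axis=0)
            A = self._L.T @ (np.maximum(wk, 1e-6)[:, None] * self._L)
            c = self._L.T @ (Y0[rows] * W[rows]).sum(axis=0)
            means[k] = np.linalg.solve(A, c)
        resid = (Y0 - (np.eye(K)[labels] @ means) @ self._L.T) * W
        theta = max(float((resid**2).sum() / W.sum()), 0.5)
        return weights, means, theta / 2.0, theta

    def _starts(self, X, Y0, W, sY2, n_obs, rng):
        """Yield (weights, means, psi, theta) initial parameter tuples."""
        n, K = Y0.shape[0], self.n_classes
        n_starts = 1 if K == 1 else self.n_starts
        if K == 1:
            base = np.zeros(n, dtype=int)
        else:
            base = self._kmeans_partition(X, rng)
        for s in range(n_starts):
            labels = base.copy()
            if s > 0:
                flip = rng.random(n) < 0.3
                labels[flip] = rng.integers(0, K, size=int(flip.sum()))
            yield self._init_from_partition(Y0, W, sY2, n_obs, labels)

    # -- public API -----------------------------------------------------
    def fit(self, X, y=None, init_params=None):
        """Fit by best-of-starts EM.

        ``init_params``, if given as (weights, means, psi, theta), is run
        as an additional warm start (used by the bootstrap likelihood
        ratio test to reuse a parent fit's parameters).
        """
        X = self._validate(X)
        self._L = self._lam().values
        W = (~np.isnan(X)).astype(float)
        Y0 = np.where(np.isnan(X), 0.0, X)
        sY2 = ((Y0**2) * W).sum(axis=1)
        n_obs = W.sum(axis=1)
        rng = np.random.default_rng(self.random_state)

        starts = []
        if init_params is not None:
            w0, m0, p0, t0 = init_params
            starts.append(
                (
                    np.asarray(w0, float).copy(),
                    np.asarray(m0, float).copy(),
                    float(p0),
                    float(t0),
                )
            )
        starts.extend(self._starts(X, Y0, W, sY2, n_obs, rng))

        best = None
        best_idx = -1
        n_discarded = 0
        for idx, (w, m, psi, theta) in enumerate(starts):
            out = self._em_run(Y0, W, sY2, n_obs, w, m, psi, theta)
            if out is None:
                n_discarded += 1
                continue
            if best is None or out[4] > best[4]:
                best, best_idx = out, idx
        if best is None:
            raise ConvergenceError(
                f"all {len(starts)} EM starts were discarded (degenerate class)"
            )
        if n_discarded:
            logger.debug("discarded %d degenerate EM starts", n_discarded)

        weights, means, psi, theta, ll, n_iter, converged, trace = best
        if not converged:
            logger.info("EM did not converge within %d iterations", self.max_iter)
        # canonical class order: descending phase-2 slope is arbitrary;
        # order by intercept then slopes for reproducible labelling
        order = np.lexsort((means[:, 2], means[:, 1], -means[:, 0]))
        self.weights_ = weights[order]
        self.means_ = means[order]
        self.intercept_var_ = float(psi)
        self.residual_var_ = float(theta)
        self.log_likelihood_ = float(ll)
        self.n_parameters_ = (self.n_classes - 1) + 3 * self.n_classes + 2
        n = X.shape[0]
        self.n_subjects_ = n
        self.bic_, self.sabic_, self.aic_ = information_criteria(ll, self.n_parameters_, n)
        self.posterior_ = self.predict_proba(X)
        self.labels_ = classify_subjects(self.posterior_)
        self.entropy_ = relative_entropy(self.posterior_, self.n_classes)
        self.n_iter_ = int(n_iter)
        self.converged_ = bool(converged)
        self.best_start_ = int(best_idx)
        self.loglik_trace_ = np.asarray(trace)
        return self

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise RuntimeError("model is not fitted")

    def score_matrix(self, X) -> np.ndarray:
        """Per-subject, per-class weighted log-densities ln(pi_k f_k)."""
        self._check_fitted()
        X = self._validate(X)
        W = (~np.isnan(X)).astype(float)
        Y0 = np.where(np.isnan(X), 0.0, X)
        WY = Y0 * W
        sY2 = (Y0 * WY).sum(axis=1)
        n_obs = W.sum(axis=1)
        S1, S2 = self._stats(W, WY, WY.sum(axis=1), sY2, self.means_)
        logw, _ = self._log_density_from_stats(
            S1, S2, n_obs, self.weights_, self.intercept_var_, self.residual_var_
        )
        return logw

    def score(self, X, y=None) -> float:
        """Total observed-data log-likelihood of ``X``."""
        return float(logsumexp(self.score_matrix(X), axis=1).sum())

    def predict_proba(self, X) -> np.ndarray:
        logw = self.score_matrix(X)
        return np.exp(logw - logsumexp(logw, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        return classify_subjects(self.predict_proba(X))

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def sample(self, n_subjects: int, random_state=None, mask: Optional[np.ndarray] = None):
        """Draw subjects from the fitted model (used by the parametric
        bootstrap).  Scores stay continuous; ``mask`` (n x T boolean), if
        given, is applied verbatim so the missingness pattern of the parent
        data is preserved."""
        self._check_fitted()
        rng = np.random.default_rng(random_state)
        L = self._lam().values
        T = L.shape[0]
        classes = rng.choice(self.n_classes, size=n_subjects, p=self.weights_)
        b = rng.normal(0.0, np.sqrt(self.intercept_var_), size=n_subjects)
        latent = self.means_[classes] @ L.T + b[:, None]
        X = latent + rng.normal(0.0, np.sqrt(self.residual_var_), size=(n_subjects, T))
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            X = np.where(mask, X, np.nan)
        return X, classes

    def fit_summary(self, seed: Optional[int] = None) -> PGMMFit:
        self._check_fitted()
        return PGMMFit(
            n_classes=self.n_classes,
            weights=self.weights_.tolist(),
            means=self.means_.tolist(),
            intercept_var=self.intercept_var_,
            residual_var=self.residual_var_,
            log_likelihood=self.log_likelihood_,
            n_parameters=self.n_parameters_,
            n_subjects=self.n_subjects_,
            bic=self.bic_,
            sabic=self.sabic_,
            aic=self.aic_,
            entropy=self.entropy_,
            n_iter=self.n_iter_,
            best_start=self.best_start_,
            converged=self.converged_,
            seed=seed if seed is not None else self.random_state,
        )


def em_fit(
    data,
    n_classes: int = 3,
    loading_matrix: Optional[LoadingMatrix] = None,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: Optional[int] = None,
) -> PiecewiseGrowthMixture:
    """Functional wrapper: fit a :class:`PiecewiseGrowthMixture` and return it."""
    model = PiecewiseGrowthMixture(
        n_classes=n_classes,
        loading_matrix=loading_matrix,
        n_starts=n_starts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    return model.fit(data)
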