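"""Mixture likelihood of a growth mixture model.

Marginalizing the random effects, the outcome vector of a subject in class k
is multivariate normal with mean ``X beta_k`` and covariance
``Sigma_k = Z Psi_k Z' + diag(theta_k)``, where X is the polynomial growth
design, Z its intercept/slope columns, Psi_k the random-effect covariance and
theta_k the occasion-specific residual variances. Missing occasions are
marginalized out by subsetting rows/columns of Sigma_k (MAR). All densities
are computed through Cholesky factors; a class covariance whose smallest
eigenvalue is at or below ``PD_EPS`` raises :class:`LikelihoodError`, which
the optimizer uses to reject a step.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp

from .dataset import LongitudinalDataset
from .parameters import GMMParameters

_LOG_2PI = float(np.log(2.0 * np.pi))

#: smallest admissible eigenvalue of a class marginal covariance
PD_EPS = 1e-10


class LikelihoodError(RuntimeError):
    """A class-conditional covariance was not positive definite (or inputs
    were otherwise unusable). Signals a rejected step, not a crash."""


def build_design_matrices(time_scores: np.ndarray, P: int) -> tuple[np.ndarray, np.ndarray]:
    """Polynomial growth-curve designs.

    Returns ``X`` (T x P) whose columns are powers 0..P-1 of the time scores,
    and ``Z = X[:, :2]`` (random intercept and linear slope only).
    """
    time_scores = np.asarray(time_scores, dtype=float)
    if P not in (2, 3, 4):
        raise ValueError("P must be 2, 3 or 4")
    t = time_scores.shape[0]
    if t < P:
        raise ValueError(f"rank deficient design: T={t} < P={P}")
    X = np.vander(time_scores, N=P, increasing=True)
    return X, X[:, :2]


def marginal_covariance(psi: np.ndarray, theta: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Class marginal covariance ``Z Psi Z' + diag(theta)`` (T x T).

    Symmetry is exact by construction. The result is *not* adjusted if it is
    non-positive-definite; use :func:`is_positive_definite` or the density
    functions, which flag the failure.
    """
    psi = np.asarray(psi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if not (np.isfinite(psi).all() and np.isfinite(theta).all() and np.isfinite(Z).all()):
        raise ValueError("non-finite covariance inputs")
    if theta.shape[0] != Z.shape[0]:
        raise ValueError("theta must have one entry per timepoint")
    sig = Z @ psi @ Z.T
    sig[np.diag_indices_from(sig)] += theta
    return 0.5 * (sig + sig.T)


def is_positive_definite(sigma: np.ndarray, eps: float = PD_EPS) -> bool:
    """True when the smallest eigenvalue exceeds ``eps``."""
    return bool(np.linalg.eigvalsh(sigma)[0] > eps)


def _chol_or_fail(sigma: np.ndarray) -> np.ndarray:
    try:
        L = cholesky(sigma, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise LikelihoodError(str(exc)) from None
    except Exception as exc:
        raise LikelihoodError(str(exc)) from None
    if np.min(np.diag(L)) ** 2 <= PD_EPS:
        raise LikelihoodError("marginal covariance numerically singular")
    return L


def _pattern_groups(mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group subject indices by missingness pattern.

    Returns a list of ``(observed_columns, subject_indices)`` pairs; a single
    pair covering everyone when the data are complete.
    """
    if mask.all():
        return [(np.arange(mask.shape[1]), np.arange(mask.shape[0]))]
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    return [
        (np.flatnonzero(patterns[p]), np.flatnonzero(inverse == p))
        for p in range(patterns.shape[0])
    ]


def class_conditional_loglik(
    data: LongitudinalDataset, params: GMMParameters
) -> np.ndarray:
    """Log density of each subject's observed outcomes under each class.

    Entry (i, k) is ``log N(y_i,obs; X_obs beta_k, Sigma_k,obs)``, with
    missing occasions marginalized by subsetting. Raises
    :class:`LikelihoodError` when a class covariance is non-PD on some
    observed coordinate subset.
    """
    X, Z = build_design_matrices(data.time_scores, params.n_growth_terms)
    K = params.n_classes
    out = np.empty((data.n_subjects, K))
    for obs, subj in _pattern_groups(data.observed_mask):
        Y = data.outcomes[np.ix_(subj, obs)]
        Xo, Zo = X[obs], Z[obs]
        d = obs.shape[0]
        for k in range(K):
            sigma = marginal_covariance(params.re_cov[k], params.residual_vars[k][obs], Zo)
            L = _chol_or_fail(sigma)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            resid = Y - Xo @ params.fixed_effects[k]
            white = solve_triangular(L, resid.T, lower=True)
            out[subj, k] = -0.5 * (d * _LOG_2PI + logdet + np.einsum("ij,ij->j", white, white))
    return out


def _weighted_logp(data: LongitudinalDataset, params: GMMParameters) -> np.ndarray:
    ll = class_conditional_loglik(data, params)
    with np.errstate(divide="ignore"):
        return ll + np.log(params.class_probs)[None, :]


def mixture_loglik(data: LongitudinalDataset, params: GMMParameters) -> float:
    """Observed-data mixture log-likelihood (log-sum-exp stabilized)."""
    return float(logsumexp(_weighted_logp(data, params), axis=1).sum())


def posterior_probs(data: LongitudinalDataset, params: GMMParameters) -> np.ndarray:
    """Posterior class membership probabilities; rows sum to one."""
    a = _weighted_logp(data, params)
    a -= logsumexp(a, axis=1, keepdims=True)
    return np.exp(a)


def fit_indices(loglik: float, p: int, N: int, posteriors: np.ndarray) -> dict[str, float]:
    """AIC, BIC, sample-size-adjusted BIC and relative entropy.

    ``aBIC`` uses the Sclove effective sample size ``(N + 2) / 24``. Relative
    entropy is ``1 - sum_i sum_k (-p_ik log p_ik) / (N log K)``, in [0, 1];
    a one-class model is reported as entropy 1 by convention.
    """
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    m2ll = -2.0 * loglik
    n_eff = (N + 2.0) / 24.0
    K = posteriors.shape[1]
    if K <= 1:
        entropy = 1.0
    else:
        pk = np.clip(posteriors, 1e-300, 1.0)
        uncert = float(-(posteriors * np.log(pk)).sum())
        entropy = 1.0 - uncert / (N * np.log(K))
        entropy = float(min(max(entropy, 0.0), 1.0))
    return {
        "AIC": m2ll + 2.0 * p,
        "BIC": m2ll + p * np.log(N),
        "aBIC": m2ll + p * np.log(n_eff),
        "entropy": entropy,
    }
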