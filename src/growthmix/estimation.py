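"""Maximum-likelihood fitting of growth mixture models under constraint schemes.

The observed-data mixture log-likelihood is maximized directly with L-BFGS-B
and hand-derived analytic gradients. Equality ties demanded by a
:class:`~growthmix.schemes.ConstraintScheme` are imposed structurally: each
tied block is a single optimization variable, so constrained models are
fitted in their reduced parameter space rather than via penalties.

Two variance parameterizations are available:

* ``bounded`` (default): residual variances enter through their logarithms
  and each random-effect covariance through its log-Cholesky factor, so every
  iterate is admissible. Mixing proportions use a multinomial logit.
* ``unbounded``: variances and the intercept-slope covariance enter raw, so
  the optimizer may report negative variance estimates (Heywood cases) as
  long as every class's implied marginal covariance stays positive definite;
  steps that break positive definiteness are rejected through a penalty.

Initialization follows a multistart protocol: a k-means base start plus
random perturbations, all run for a short burst, the best few run to
convergence, best final log-likelihood wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from sklearn.cluster import KMeans

from .dataset import LongitudinalDataset
from .likelihood import (
    PD_EPS,
    _pattern_groups,
    build_design_matrices,
    fit_indices,
)
from .parameters import GMMParameters, count_free_parameters
from .schemes import ConstraintScheme, get_scheme

_LOG_2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1e10


@dataclass
class FitOptions:
    """Knobs of the multistart ML protocol.

    ``n_starts`` random starts are each run for ``short_run_iters`` L-BFGS
    iterations; the ``n_final`` best are continued to convergence
    (``max_iters`` cap, relative log-likelihood tolerance ``rel_tol``).
    ``perturb_scale`` is the log-normal noise scale applied to the base
    start's variance parameters (zero reproduces the base start exactly).
    """

    n_starts: int = 20
    short_run_iters: int = 50
    n_final: int = 5
    max_iters: int = 2000
    rel_tol: float = 1e-8
    variance_mode: str = "bounded"
    perturb_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_final > self.n_starts:
            raise ValueError("n_final cannot exceed n_starts")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.variance_mode not in ("bounded", "unbounded"):
            raise ValueError("variance_mode must be 'bounded' or 'unbounded'")


@dataclass
class FittedModel:
    """A converged (or failed) GMM fit plus its diagnostics."""

    scheme: ConstraintScheme
    params: Optional[GMMParameters]
    loglik: float
    n_params: int
    posteriors: Optional[np.ndarray]
    indices: dict
    converged: bool
    negative_variance: bool = False
    boundary_variance: bool = False
    best_loglik_replicated: bool = False
    start_logliks: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.id,
            "params": None if self.params is None else self.params.to_dict(),
            "loglik": None if not np.isfinite(self.loglik) else float(self.loglik),
            "n_params": int(self.n_params),
            "indices": {
                k: (None if not np.isfinite(v) else float(v))
                for k, v in self.indices.items()
            },
            "converged": bool(self.converged),
            "negative_variance": bool(self.negative_variance),
            "boundary_variance": bool(self.boundary_variance),
            "best_loglik_replicated": bool(self.best_loglik_replicated),
            "start_logliks": [float(v) for v in self.start_logliks],
        }


_NAN_INDICES = {"AIC": np.nan, "BIC": np.nan, "aBIC": np.nan, "entropy": np.nan}


# --------------------------------------------------------------------------
# parameter vector <-> structured parameters
# --------------------------------------------------------------------------


class _Layout:
    """Packing of the reduced (tie-respecting) parameter vector.

    Order: class logits (K-1), growth coefficients (K*P), one triple per
    distinct random-effect covariance, one value per distinct residual
    variance cell. Bounded mode stores log-Cholesky / log-variance entries;
    unbounded mode stores raw (co)variances.
    """

    def __init__(self, scheme: ConstraintScheme, K: int, T: int, P: int, mode: str):
        self.scheme, self.K, self.T, self.P, self.mode = scheme, K, T, P, mode
        self.n_psi_sets = 1 if scheme.random_effects_tied_over_classes else K
        self.theta_rows = 1 if scheme.residual_tied_over_classes else K
        self.theta_cols = 1 if scheme.residual_tied_over_time else T
        self.i_eta = slice(0, K - 1)
        o = K - 1
        self.i_beta = slice(o, o + K * P)
        o += K * P
        self.i_psi = slice(o, o + 3 * self.n_psi_sets)
        o += 3 * self.n_psi_sets
        self.i_theta = slice(o, o + self.theta_rows * self.theta_cols)
        self.size = o + self.theta_rows * self.theta_cols

    # -- packing -----------------------------------------------------------

    def pack(self, params: GMMParameters) -> np.ndarray:
        K, P = self.K, self.P
        x = np.empty(self.size)
        pi = np.clip(params.class_probs, 1e-8, None)
        x[self.i_eta] = np.log(pi[:-1]) - np.log(pi[-1])
        x[self.i_beta] = params.fixed_effects.ravel()
        psis = np.empty((self.n_psi_sets, 3))
        for s in range(self.n_psi_sets):
            psi = params.re_cov[s]
            if self.mode == "bounded":
                psi = psi + 1e-8 * np.eye(2)
                L = cholesky(psi, lower=True)
                psis[s] = (math.log(L[0, 0]), L[1, 0], math.log(L[1, 1]))
            else:
                psis[s] = (psi[0, 0], psi[0, 1], psi[1, 1])
        x[self.i_psi] = psis.ravel()
        th = params.residual_vars[: self.theta_rows, : self.theta_cols]
        x[self.i_theta] = (
            np.log(np.clip(th, 1e-8, None)).ravel() if self.mode == "bounded" else th.ravel()
        )
        return x

    def unpack(self, x: np.ndarray):
        """Return (pi, beta(K,P), psi_full(K,2,2), theta_full(K,T), cache)."""
        K, T, P = self.K, self.T, self.P
        eta = np.append(x[self.i_eta], 0.0)
        eta -= eta.max()
        e = np.exp(eta)
        pi = e / e.sum()
        beta = x[self.i_beta].reshape(K, P)
        psi_raw = x[self.i_psi].reshape(self.n_psi_sets, 3)
        psi_sets = np.empty((self.n_psi_sets, 2, 2))
        chol_sets = None
        if self.mode == "bounded":
            chol_sets = np.zeros((self.n_psi_sets, 2, 2))
            for s in range(self.n_psi_sets):
                a, c, b = psi_raw[s]
                L = np.array([[math.exp(a), 0.0], [c, math.exp(b)]])
                chol_sets[s] = L
                psi_sets[s] = L @ L.T
        else:
            for s in range(self.n_psi_sets):
                p0, p01, p1 = psi_raw[s]
                psi_sets[s] = [[p0, p01], [p01, p1]]
        th = x[self.i_theta].reshape(self.theta_rows, self.theta_cols)
        theta_mat = np.exp(th) if self.mode == "bounded" else th
        theta_full = np.ascontiguousarray(np.broadcast_to(theta_mat, (K, T)))
        set_of_class = np.zeros(K, dtype=int) if self.n_psi_sets == 1 else np.arange(K)
        psi_full = psi_sets[set_of_class]
        cache = {"chol_sets": chol_sets, "theta_mat": theta_mat, "pi": pi}
        return pi, beta, psi_full, theta_full, cache

    def contract_grad(self, g_W, g_beta, g_psi_full, g_theta_full, cache) -> np.ndarray:
        """Map gradients w.r.t. expanded parameters back to the packed vector.

        ``g_W`` holds per-class posterior mass sums; ``g_psi_full`` the
        symmetric full-matrix gradients w.r.t. each Psi_k; ``g_theta_full``
        the gradient w.r.t. each residual-variance cell. All are gradients of
        the *log-likelihood* (maximization); negation happens in the caller.
        """
        K = self.K
        g = np.empty(self.size)
        pi = cache["pi"]
        N = g_W.sum()
        g[self.i_eta] = (g_W - pi * N)[:-1]
        g[self.i_beta] = g_beta.ravel()
        if self.n_psi_sets == 1:
            g_sets = g_psi_full.sum(axis=0, keepdims=True)
        else:
            g_sets = g_psi_full
        gp = np.empty((self.n_psi_sets, 3))
        for s in range(self.n_psi_sets):
            G = g_sets[s]
            if self.mode == "bounded":
                L = cache["chol_sets"][s]
                M = 2.0 * G @ L
                gp[s] = (M[0, 0] * L[0, 0], M[1, 0], M[1, 1] * L[1, 1])
            else:
                gp[s] = (G[0, 0], 2.0 * G[0, 1], G[1, 1])
        g[self.i_psi] = gp.ravel()
        gt = g_theta_full
        if self.theta_rows == 1:
            gt = gt.sum(axis=0, keepdims=True)
        if self.theta_cols == 1:
            gt = gt.sum(axis=1, keepdims=True)
        if self.mode == "bounded":
            gt = gt * cache["theta_mat"]
        g[self.i_theta] = gt.ravel()
        return g

    def bounds(self):
        if self.mode != "bounded":
            return None
        b = [(None, None)] * self.size
        for i in range(*self.i_eta.indices(self.size)):
            b[i] = (-30.0, 30.0)
        psi_lo = self.i_psi.indices(self.size)[0]
        for s in range(self.n_psi_sets):
            b[psi_lo + 3 * s] = (-12.0, 12.0)  # log L00
            b[psi_lo + 3 * s + 2] = (-12.0, 12.0)  # log L11
        for i in range(*self.i_theta.indices(self.size)):
            b[i] = (-25.0, 25.0)
        return b

    def to_parameters(self, x: np.ndarray) -> GMMParameters:
        pi, beta, psi_full, theta_full, _ = self.unpack(x)
        return GMMParameters(pi, beta, psi_full.copy(), theta_full.copy())


# --------------------------------------------------------------------------
# objective with analytic gradient
# --------------------------------------------------------------------------


class _Objective:
    def __init__(self, data: LongitudinalDataset, layout: _Layout):
        self.layout = layout
        self.X, self.Z = build_design_matrices(data.time_scores, layout.P)
        self.groups = [
            (obs, subj, data.outcomes[np.ix_(subj, obs)])
            for obs, subj in _pattern_groups(data.observed_mask)
        ]
        self.N = data.n_subjects
        self.T = data.n_timepoints

    def __call__(self, x: np.ndarray):
        lay = self.layout
        K, T = lay.K, self.T
        pi, beta, psi_full, theta_full, cache = lay.unpack(x)

        # full-grid covariances; principal submatrices inherit PD-ness
        chols_full = []
        violation = 0.0
        for k in range(K):
            sigma = self.Z @ psi_full[k] @ self.Z.T
            sigma[np.diag_indices_from(sigma)] += theta_full[k]
            try:
                L = cholesky(sigma, lower=True)
                if np.min(np.diag(L)) ** 2 <= PD_EPS:
                    raise np.linalg.LinAlgError("singular")
            except Exception:
                ev = np.linalg.eigvalsh(0.5 * (sigma + sigma.T))[0]
                violation += max(0.0, PD_EPS - ev) + 1.0
                chols_full.append(None)
                continue
            chols_full.append(L)
        if violation > 0.0:
            return _PENALTY * (1.0 + violation), np.zeros(lay.size)

        ll = np.empty((self.N, K))
        stash = []
        for obs, subj, Y in self.groups:
            d = obs.shape[0]
            Xo, Zo = self.X[obs], self.Z[obs]
            for k in range(K):
                if d == T:
                    L = chols_full[k]
                else:
                    sigma = Zo @ psi_full[k] @ Zo.T
                    sigma[np.diag_indices_from(sigma)] += theta_full[k][obs]
                    try:
                        L = cholesky(sigma, lower=True)
                    except Exception:
                        return _PENALTY, np.zeros(lay.size)
                logdet = 2.0 * np.log(np.diag(L)).sum()
                R = Y - Xo @ beta[k]
                U = solve_triangular(L, R.T, lower=True, check_finite=False)
                ll[subj, k] = -0.5 * (d * _LOG_2PI + logdet + np.einsum("ij,ij->j", U, U))
                stash.append((k, obs, subj, Xo, Zo, L, R))

        A = ll + np.log(pi)[None, :]
        m = A.max(axis=1)
        lse = m + np.log(np.exp(A - m[:, None]).sum(axis=1))
        f = -lse.sum()
        if not np.isfinite(f):
            return _PENALTY, np.zeros(lay.size)
        W_all = np.exp(A - lse[:, None])  # posterior weights, N x K

        g_beta = np.zeros_like(beta)
        g_psi = np.zeros((K, 2, 2))
        g_theta = np.zeros((K, T))
        eye_cache = {}
        for k, obs, subj, Xo, Zo, L, R in stash:
            d = obs.shape[0]
            w = W_all[subj, k]
            wsum = w.sum()
            I = eye_cache.setdefault(d, np.eye(d))
            Ainv = cho_solve((L, True), I, check_finite=False)
            Rw = R * w[:, None]
            S = Ainv @ (R.T @ Rw) @ Ainv
            Ghat = 0.5 * (S - wsum * Ainv)
            g_beta[k] += Xo.T @ (Ainv @ (R.T @ w))
            g_theta[k, obs] += np.diag(Ghat)
            g_psi[k] += Zo.T @ Ghat @ Zo
        g_W = W_all.sum(axis=0)
        grad = -self.layout.contract_grad(g_W, g_beta, g_psi, g_theta, cache)
        return f, grad


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------


def _class_moments(data, X, Z, labels, K, min_var=1e-3):
    """Per-class OLS growth curves and moment starts for Psi and theta."""
    T, P = X.shape[0], X.shape[1]
    beta = np.zeros((K, P))
    psi = np.zeros((K, 2, 2))
    theta = np.full((K, T), np.nan)
    pinv2 = np.linalg.pinv(Z)
    for k in range(K):
        members = np.flatnonzero(labels == k)
        rows, ys = [], []
        for i in members:
            o = np.flatnonzero(data.observed_mask[i])
            rows.append(X[o])
            ys.append(data.outcomes[i, o])
        Xs = np.vstack(rows)
        yv = np.concatenate(ys)
        beta[k] = np.linalg.lstsq(Xs, yv, rcond=None)[0]
        # per-subject intercept/slope coefficients
        coefs = []
        resid_by_t = [[] for _ in range(T)]
        for i in members:
            o = np.flatnonzero(data.observed_mask[i])
            r = data.outcomes[i, o] - X[o] @ beta[k]
            for j, t in enumerate(o):
                resid_by_t[t].append(r[j])
            if o.shape[0] >= 2:
                if o.shape[0] == T:
                    coefs.append(pinv2 @ data.outcomes[i])
                else:
                    coefs.append(np.linalg.lstsq(Z[o], data.outcomes[i, o], rcond=None)[0])
        coefs = np.asarray(coefs)
        if coefs.shape[0] >= 3:
            dev = coefs - coefs.mean(axis=0)
            v = 0.5 * (dev**2).mean(axis=0)
        else:
            v = np.array([0.1, 0.05])
        psi[k, 0, 0] = max(v[0], min_var)
        psi[k, 1, 1] = max(v[1], min_var)
        for t in range(T):
            vals = np.asarray(resid_by_t[t])
            theta[k, t] = max(0.5 * vals.var(), min_var) if vals.size >= 2 else 0.25
    return beta, psi, theta


def _apply_ties(pi, beta, psi, theta, scheme, weights):
    """Average moment starts over tied blocks so the base start is admissible
    in the reduced parameter space."""
    w = weights / weights.sum()
    if scheme.random_effects_tied_over_classes:
        pooled = np.einsum("k,kij->ij", w, psi)
        psi = np.repeat(pooled[None], psi.shape[0], axis=0)
    if scheme.residual_tied_over_classes:
        pooled = w @ theta
        theta = np.repeat(pooled[None], theta.shape[0], axis=0)
    if scheme.residual_tied_over_time:
        theta = np.repeat(theta.mean(axis=1, keepdims=True), theta.shape[1], axis=1)
    return pi, beta, psi, theta


def initialize_starts(
    data: LongitudinalDataset,
    K: int,
    scheme: ConstraintScheme,
    options: FitOptions,
    P: int = 2,
) -> list[GMMParameters]:
    """Multistart initial values: k-means base start plus perturbations.

    The base start clusters complete-case trajectory vectors with k-means
    (subjects with missingness are assigned to the nearest centroid on their
    observed coordinates), then takes class-wise OLS growth curves and moment
    estimates of the variance components, tied per the scheme. Remaining
    starts perturb the base multiplicatively (log-normal) on variances and
    additively on means; everything is deterministic given ``options.seed``.
    """
    scheme = get_scheme(scheme)
    if K < 1:
        raise ValueError("K must be at least 1")
    if K > data.n_subjects:
        raise ValueError("more classes than subjects")
    X, Z = build_design_matrices(data.time_scores, P)
    n, T = data.n_subjects, data.n_timepoints
    rng = np.random.default_rng(options.seed)

    if K == 1:
        labels = np.zeros(n, dtype=int)
    else:
        complete = data.observed_mask.all(axis=1)
        feats = data.outcomes.copy()
        col_means = np.nanmean(np.where(data.observed_mask, data.outcomes, np.nan), axis=0)
        fill = np.broadcast_to(col_means, feats.shape)
        feats = np.where(data.observed_mask, feats, fill)
        fit_rows = feats[complete] if complete.sum() >= max(K, 10) else feats
        km = KMeans(n_clusters=K, n_init=5, random_state=options.seed % (2**31)).fit(fit_rows)
        labels = np.empty(n, dtype=int)
        for i in range(n):
            o = data.observed_mask[i]
            if o.all():
                labels[i] = km.predict(feats[i][None])[0]
            else:
                d2 = ((km.cluster_centers_[:, o] - data.outcomes[i, o]) ** 2).sum(axis=1)
                labels[i] = int(np.argmin(d2))
        # guard against an empty cluster after reassignment
        for k in range(K):
            if not (labels == k).any():
                far = np.argsort(((feats - km.cluster_centers_[k]) ** 2).sum(axis=1))
                labels[far[0]] = k

    counts = np.bincount(labels, minlength=K).astype(float)
    pi = np.clip(counts / n, 0.02, None)
    pi /= pi.sum()
    beta, psi, theta = _class_moments(data, X, Z, labels, K)
    pi, beta, psi, theta = _apply_ties(pi, beta, psi, theta, scheme, counts)
    base = GMMParameters(pi, beta, psi, theta)

    sd_y = float(np.std(data.outcomes[data.observed_mask]))
    starts = [base]
    scale = options.perturb_scale
    for _ in range(options.n_starts - 1):
        b = beta + scale * 0.4 * sd_y * rng.standard_normal(beta.shape)
        ps = psi.copy()
        ps[:, 0, 0] *= np.exp(scale * rng.standard_normal(K))
        ps[:, 1, 1] *= np.exp(scale * rng.standard_normal(K))
        th = theta * np.exp(scale * rng.standard_normal(theta.shape))
        eta = np.log(pi) + scale * 0.5 * rng.standard_normal(K)
        p = np.exp(eta - eta.max())
        p /= p.sum()
        _, b2, ps2, th2 = _apply_ties(p, b, ps, th, scheme, counts)
        starts.append(GMMParameters(p, b2, ps2, th2))
    return starts


# --------------------------------------------------------------------------
# the fitter
# --------------------------------------------------------------------------


def _run_opt(obj, x0, maxiter, rel_tol, bounds):
    return minimize(
        obj,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": rel_tol, "gtol": 1e-5, "maxls": 40},
    )


def fit_gmm(
    data: LongitudinalDataset,
    K: int,
    scheme: "str | ConstraintScheme",
    options: FitOptions | None = None,
    P: int = 2,
) -> FittedModel:
    """Fit a K-class growth mixture model under a constraint scheme.

    Runs the multistart protocol of :class:`FitOptions` and returns the best
    converged solution with classes presented in ascending order of fitted
    intercept mean. Never raises on optimization failure: if every start
    fails, the returned model has ``converged=False`` and NaN fit indices so
    simulation loops can tabulate non-convergence.
    """
    scheme = get_scheme(scheme)
    options = options or FitOptions()
    n_par = count_free_parameters(scheme, K, data.n_timepoints, P)
    layout = _Layout(scheme, K, data.n_timepoints, P, options.variance_mode)
    starts = initialize_starts(data, K, scheme, options, P=P)
    obj = _Objective(data, layout)
    bounds = layout.bounds()

    shorts = []
    for idx, p0 in enumerate(starts):
        try:
            res = _run_opt(obj, layout.pack(p0), options.short_run_iters, options.rel_tol, bounds)
            if np.isfinite(res.fun) and res.fun < _PENALTY / 2:
                shorts.append((res.fun, idx, res.x))
        except Exception:
            continue
    if not shorts:
        return FittedModel(scheme, None, np.nan, n_par, None, dict(_NAN_INDICES), False)
    shorts.sort(key=lambda t: (t[0], t[1]))

    finals = []
    for fun0, idx, xs in shorts[: options.n_final]:
        try:
            res = _run_opt(obj, xs, options.max_iters, options.rel_tol, bounds)
            if np.isfinite(res.fun) and res.fun < _PENALTY / 2:
                finals.append((res.fun, idx, res.x, bool(res.success)))
        except Exception:
            continue
    if not finals:
        return FittedModel(scheme, None, np.nan, n_par, None, dict(_NAN_INDICES), False)
    finals.sort(key=lambda t: (t[0], t[1]))
    fun, idx, xbest, success = finals[0]
    loglik = -fun
    start_lls = [-f for f, *_ in finals]
    replicated = len(finals) > 1 and abs(finals[1][0] - fun) <= 1e-4 * max(1.0, abs(fun))

    params = layout.to_parameters(xbest)
    converged = success
    if options.variance_mode == "unbounded":
        Xd, Zd = build_design_matrices(data.time_scores, P)
        for k in range(K):
            sig = Zd @ params.re_cov[k] @ Zd.T + np.diag(params.residual_vars[k])
            if np.linalg.eigvalsh(sig)[0] <= PD_EPS:
                converged = False

    params, order = params.sorted_by_intercept()
    from .likelihood import posterior_probs  # late import avoids cycle at module load

    post = posterior_probs(data, params)
    indices = fit_indices(loglik, n_par, data.n_subjects, post)

    variances = np.concatenate(
        [params.residual_vars.ravel(), params.re_cov[:, 0, 0], params.re_cov[:, 1, 1]]
    )
    negative = options.variance_mode == "unbounded" and bool((variances < 0).any())
    boundary = options.variance_mode == "bounded" and bool((variances < 1e-6).any())

    return FittedModel(
        scheme=scheme,
        params=params,
        loglik=loglik,
        n_params=n_par,
        posteriors=post,
        indices=indices,
        converged=converged,
        negative_variance=negative,
        boundary_variance=boundary,
        best_loglik_replicated=replicated,
        start_logliks=start_lls,
    )
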