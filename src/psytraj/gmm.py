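"""Finite mixtures of Gaussian latent growth curves, estimated from scratch.

Each latent class k has a polynomial mean trajectory X @ beta_k over T
follow-up years; optionally a subject-level random intercept and slope with
covariance Sigma_b shared across classes; and a shared residual variance
sigma2.  Missing years are handled by full-information likelihood: each
subject contributes the marginal multivariate normal density of their
observed years only (missing-at-random).

Estimation is EM over class membership with the random effects integrated
analytically.  Cheap closed-form conditional-maximisation updates (random
effects treated as latent) carry each start most of the way; the surviving
starts are refined with the profile M-step (numerical maximisation of the
posterior-weighted marginal likelihood over the variance components, with
the class curves profiled out by generalised least squares).  Both update
families are monotone in the observed-data log-likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import logsumexp

from .cohort import AnnualSeries, annual_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthMixtureSpec",
    "GrowthMixtureFit",
    "design_matrices",
    "class_conditional_loglik",
    "fit_gmm",
    "compute_bic",
    "compute_entropy",
    "avg_posterior_by_modal_class",
    "robust_standard_errors",
    "RobustSEResult",
    "simulate_from_fit",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GrowthMixtureSpec:
    """Model form and estimation settings for one growth mixture fit."""

    n_classes: int = 4
    degree: int = 2  # 1 linear, 2 quadratic, 3 cubic (0 = intercept-only, no RE)
    random_effects: str = "intercept_slope"  # or "none"
    n_starts: int = 50
    n_final: int = 5  # starts refined to full convergence
    short_iter: int = 60  # closed-form EM iterations per exploratory start
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.degree not in (0, 1, 2, 3):
            raise ValueError("degree must be 0, 1, 2 or 3")
        if self.random_effects not in ("none", "intercept_slope"):
            raise ValueError("random_effects must be 'none' or 'intercept_slope'")
        if self.degree == 0 and self.random_effects != "none":
            raise ValueError("intercept-only models cannot carry random slopes")

    @property
    def has_re(self) -> bool:
        return self.random_effects == "intercept_slope"

    def n_params(self) -> int:
        p = self.degree + 1
        k = self.n_classes
        return k * p + (k - 1) + 1 + (3 if self.has_re else 0)


@dataclass
class GrowthMixtureFit:
    """Maximum-likelihood fit of a growth mixture model."""

    spec: GrowthMixtureSpec
    pi: np.ndarray  # (K,)
    beta: np.ndarray  # (K, degree+1), centred-time basis
    Sigma_b: np.ndarray | None  # (2, 2) or None
    sigma2: float
    loglik: float
    posteriors: np.ndarray  # (n, K)
    n_params: int
    converged: bool
    n_used: int
    T: int
    subject_ids: list[str] = field(default_factory=list)
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    @property
    def bic(self) -> float:
        return compute_bic(self.loglik, self.n_params, self.n_used)

    @property
    def entropy(self) -> float:
        return compute_entropy(self.posteriors)

    def mean_curves(self) -> np.ndarray:
        """Fitted class mean trajectories, shape (K, T), on the months-per-year scale."""
        X, _ = design_matrices(self.T, self.spec.degree)
        return self.beta @ X.T

    @property
    def modal_class(self) -> np.ndarray:
        return np.argmax(self.posteriors, axis=1)

    @property
    def min_class_share(self) -> float:
        return float(self.pi.min())


def design_matrices(T: int, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed- and random-effect design matrices for T annual time points.

    Time is centred at mid-follow-up, t_c = t - (T+1)/2 for t = 1..T, which
    decorrelates the polynomial coefficients.  Z is the first two columns of
    X (intercept and linear term).
    """
    if T < degree + 1:
        raise ValueError(
            f"T={T} time points cannot identify a degree-{degree} polynomial "
            f"({degree + 1} coefficients)"
        )
    t = np.arange(1, T + 1, dtype=float) - (T + 1) / 2.0
    X = np.column_stack([t**d for d in range(degree + 1)])
    Z = X[:, :2] if X.shape[1] >= 2 else X
    return X, Z


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


def class_conditional_loglik(
    y_i: AnnualSeries | np.ndarray,
    beta_k: np.ndarray,
    Sigma_b: np.ndarray | None,
    sigma2: float,
    X: np.ndarray,
    Z: np.ndarray,
) -> float:
    """Marginal log-density of one subject's observed years under class k.

    The observed entries of y are multivariate normal with mean the observed
    rows of X @ beta_k and covariance the corresponding block of
    Z Sigma_b Z' + sigma2 I; missing years are handled by row subsetting.
    """
    if isinstance(y_i, AnnualSeries):
        sid, y = y_i.subject_id, y_i.y
    else:
        sid, y = "<array>", np.asarray(y_i, dtype=float)
    obs = ~np.isnan(y)
    if not obs.any():
        raise ValueError(f"subject {sid!r} has no observed years")
    r = y[obs] - X[obs] @ beta_k
    m = int(obs.sum())
    if Sigma_b is None:
        return float(-0.5 * (m * (_LOG2PI + np.log(sigma2)) + (r**2).sum() / sigma2))
    Zo = Z[obs]
    V = Zo @ Sigma_b @ Zo.T + sigma2 * np.eye(m)
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular within-class covariance for subject {sid!r}") from exc
    logdet = 2.0 * np.log(np.diag(c)).sum()
    quad = float(r @ cho_solve((c, low), r))
    return float(-0.5 * (m * _LOG2PI + logdet + quad))


class _Pattern:
    """Subjects sharing one missing-data pattern."""

    __slots__ = ("rows", "cols", "Y", "Xo", "Zo", "m")

    def __init__(self, rows, cols, Y, X, Z):
        self.rows = rows
        self.cols = cols
        self.Y = Y[np.ix_(rows, cols)]
        self.Xo = X[cols]
        self.Zo = Z[cols]
        self.m = cols.size


def _build_patterns(Y: np.ndarray, X: np.ndarray, Z: np.ndarray) -> list[_Pattern]:
    obs = ~np.isnan(Y)
    if not obs.any(axis=1).all():
        bad = int(np.argmin(obs.any(axis=1)))
        raise ValueError(f"subject at row {bad} has no observed years")
    keys = obs @ (1 << np.arange(Y.shape[1], dtype=np.int64))
    patterns = []
    for key in np.unique(keys):
        rows = np.flatnonzero(keys == key)
        cols = np.flatnonzero(obs[rows[0]])
        patterns.append(_Pattern(rows, cols, Y, X, Z))
    return patterns


def _loglik_matrix(
    patterns: list[_Pattern],
    beta: np.ndarray,
    Sigma_b: np.ndarray | None,
    sigma2: float,
    n: int,
) -> np.ndarray:
    """n x K matrix of class-conditional marginal log-likelihoods."""
    K = beta.shape[0]
    ll = np.empty((n, K))
    for pat in patterns:
        mu = pat.Xo @ beta.T  # (m, K)
        diff = pat.Y[:, :, None] - mu[None, :, :]  # (ng, m, K)
        if Sigma_b is None:
            ll[pat.rows] = -0.5 * (
                pat.m * (_LOG2PI + np.log(sigma2)) + (diff**2).sum(axis=1) / sigma2
            )
        else:
            V = pat.Zo @ Sigma_b @ pat.Zo.T + sigma2 * np.eye(pat.m)
            c = np.linalg.cholesky(V)
            logdet = 2.0 * np.log(np.diag(c)).sum()
            flat = diff.transpose(1, 0, 2).reshape(pat.m, -1)
            sol = solve_triangular(c, flat, lower=True)
            quad = (sol**2).sum(axis=0).reshape(diff.shape[0], K)
            ll[pat.rows] = -0.5 * (pat.m * _LOG2PI + logdet + quad)
    return ll


def _e_step(patterns, pi, beta, Sigma_b, sigma2, n):
    ll = _loglik_matrix(patterns, beta, Sigma_b, sigma2, n)
    logw = np.log(pi)[None, :] + ll
    norm = logsumexp(logw, axis=1)
    P = np.exp(logw - norm[:, None])
    return P, float(norm.sum())


class _DegenerateStart(RuntimeError):
    pass


def _check_degenerate(pi: np.ndarray, n: int) -> None:
    if pi.min() < 1.0 / n:
        raise _DegenerateStart(f"class share {pi.min():.4g} fell below 1/n")


def _m_step_closed(patterns, P, beta_old, Sigma_b, sigma2, n, p):
    """Closed-form conditional-maximisation update (random effects latent)."""
    K = P.shape[1]
    pi = P.mean(axis=0)
    new_Sigma = None
    bhat = {}  # pattern index -> (ng, K, 2)

    if Sigma_b is not None:
        S = np.zeros((2, 2))
        for gi, pat in enumerate(patterns):
            V = pat.Zo @ Sigma_b @ pat.Zo.T + sigma2 * np.eye(pat.m)
            c, low = cho_factor(V, lower=True)
            ZS = pat.Zo @ Sigma_b  # (m, 2)
            Wb = cho_solve((c, low), ZS)  # V^{-1} Z Sigma_b
            Bvar = Sigma_b - ZS.T @ Wb
            mu = pat.Xo @ beta_old.T
            R = pat.Y[:, :, None] - mu[None, :, :]  # (ng, m, K)
            b = np.einsum("imk,md->ikd", R, Wb)  # (ng, K, 2)
            bhat[gi] = (b, Bvar)
            Pg = P[pat.rows]  # (ng, K)
            S += np.einsum("ik,ika,ikb->ab", Pg, b, b) + Pg.sum() * Bvar
        new_Sigma = S / n
        # keep the matrix symmetric against accumulation error
        new_Sigma = 0.5 * (new_Sigma + new_Sigma.T)

    # class curves by posterior-weighted least squares on the b-adjusted outcome
    A = np.zeros((K, p, p))
    cvec = np.zeros((K, p))
    for gi, pat in enumerate(patterns):
        Pg = P[pat.rows]
        XtX = pat.Xo.T @ pat.Xo
        A += Pg.sum(axis=0)[:, None, None] * XtX[None]
        if Sigma_b is None:
            cvec += np.einsum("tp,ik,it->kp", pat.Xo, Pg, pat.Y)
        else:
            b, _ = bhat[gi]
            yadj = pat.Y[:, None, :] - np.einsum("ikd,md->ikm", b, pat.Zo)  # (ng, K, m)
            cvec += np.einsum("tp,ik,ikt->kp", pat.Xo, Pg, yadj)
    beta = np.stack([np.linalg.solve(A[k] + 1e-10 * np.eye(p), cvec[k]) for k in range(K)])

    # residual variance given the new curves
    num = 0.0
    den = 0.0
    for gi, pat in enumerate(patterns):
        Pg = P[pat.rows]
        mu = pat.Xo @ beta.T
        if Sigma_b is None:
            diff = pat.Y[:, :, None] - mu[None, :, :]
            num += (Pg * (diff**2).sum(axis=1)).sum()
        else:
            b, Bvar = bhat[gi]
            e = (
                pat.Y[:, None, :]
                - mu.T[None, :, :]
                - np.einsum("ikd,md->ikm", b, pat.Zo)
            )
            num += (Pg * (e**2).sum(axis=2)).sum()
            num += Pg.sum() * np.trace(pat.Zo @ Bvar @ pat.Zo.T)
        den += Pg.shape[0] * pat.m
    sigma2_new = max(num / den, 1e-8)
    return pi, beta, new_Sigma, sigma2_new


def _profile_theta_pack(Sigma_b: np.ndarray, sigma2: float) -> np.ndarray:
    sd0 = np.sqrt(max(Sigma_b[0, 0], 1e-10))
    sd1 = np.sqrt(max(Sigma_b[1, 1], 1e-10))
    r = np.clip(Sigma_b[0, 1] / (sd0 * sd1), -0.999, 0.999)
    return np.array([np.log(sd0), np.log(sd1), np.arctanh(r), 0.5 * np.log(sigma2)])


def _profile_theta_unpack(th: np.ndarray) -> tuple[np.ndarray, float]:
    sd0, sd1 = np.exp(np.clip(th[0], -8, 4)), np.exp(np.clip(th[1], -8, 4))
    r = np.tanh(np.clip(th[2], -6, 6))
    sigma2 = np.exp(2.0 * np.clip(th[3], -8, 4))
    Sigma_b = np.array([[sd0**2, r * sd0 * sd1], [r * sd0 * sd1, sd1**2]])
    return Sigma_b, float(sigma2)


def _gls_beta(patterns, P, Sigma_b, sigma2, p):
    """Posterior-weighted GLS curves given the variance components."""
    K = P.shape[1]
    A = np.zeros((K, p, p))
    cvec = np.zeros((K, p))
    for pat in patterns:
        if Sigma_b is None:
            Vi_X = pat.Xo / sigma2
        else:
            V = pat.Zo @ Sigma_b @ pat.Zo.T + sigma2 * np.eye(pat.m)
            c, low = cho_factor(V, lower=True)
            Vi_X = cho_solve((c, low), pat.Xo)
        XtViX = pat.Xo.T @ Vi_X
        Pg = P[pat.rows]
        A += Pg.sum(axis=0)[:, None, None] * XtViX[None]
        cvec += np.einsum("tp,ik,it->kp", Vi_X, Pg, pat.Y)
    return np.stack([np.linalg.solve(A[k] + 1e-10 * np.eye(p), cvec[k]) for k in range(K)])


def _m_step_profile(patterns, P, beta_old, Sigma_b, sigma2, n, p):
    """Numerically maximise the posterior-weighted marginal likelihood over
    the variance components, profiling the class curves by GLS."""

    def negQ(th):
        Sb, s2 = _profile_theta_unpack(th)
        try:
            beta = _gls_beta(patterns, P, Sb, s2, p)
            ll = _loglik_matrix(patterns, beta, Sb, s2, n)
        except np.linalg.LinAlgError:
            return 1e12
        return -float((P * ll).sum())

    th0 = _profile_theta_pack(Sigma_b, sigma2)
    f0 = negQ(th0)
    res = minimize(negQ, th0, method="L-BFGS-B", options={"maxiter": 60, "ftol": 1e-12})
    th = res.x if res.fun <= f0 else th0
    Sb, s2 = _profile_theta_unpack(th)
    beta = _gls_beta(patterns, P, Sb, s2, p)
    return P.mean(axis=0), beta, Sb, s2


def _em(
    patterns,
    init,
    n,
    p,
    has_re,
    max_iter,
    tol,
    refine=False,
    check_degenerate=True,
):
    """Run EM from ``init``; returns (params, loglik, trace, converged)."""
    pi, beta, Sigma_b, sigma2 = init
    trace = []
    P, ll = _e_step(patterns, pi, beta, Sigma_b, sigma2, n)
    trace.append(ll)
    converged = False
    for it in range(max_iter):
        if check_degenerate:
            _check_degenerate(P.mean(axis=0), n)
        if refine and has_re:
            pi, beta, Sigma_b, sigma2 = _m_step_profile(
                patterns, P, beta, Sigma_b, sigma2, n, p
            )
        else:
            pi, beta, Sigma_b, sigma2 = _m_step_closed(
                patterns, P, beta, Sigma_b, sigma2, n, p
            )
        P, ll_new = _e_step(patterns, pi, beta, Sigma_b, sigma2, n)
        trace.append(ll_new)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return (pi, beta, Sigma_b, sigma2), ll, np.array(trace), converged, P


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def _lloyd_kmeans(Yimp: np.ndarray, K: int, rng: np.random.Generator, n_iter: int = 10):
    n = Yimp.shape[0]
    centres = Yimp[rng.choice(n, size=K, replace=False)]
    labels = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        d = ((Yimp[:, None, :] - centres[None]) ** 2).sum(axis=2)
        labels = d.argmin(axis=1)
        for k in range(K):
            members = Yimp[labels == k]
            if members.shape[0]:
                centres[k] = members.mean(axis=0)
            else:
                centres[k] = Yimp[rng.integers(n)]
    return labels


def _init_from_labels(Y, X, labels, K, p, has_re, rng):
    n, T = Y.shape
    obs = ~np.isnan(Y)
    beta = np.zeros((K, p))
    resid_ss = 0.0
    resid_n = 0
    for k in range(K):
        members = np.flatnonzero(labels == k)
        rows, cols = np.nonzero(obs[members])
        Xc = X[cols]
        yc = Y[members][obs[members]]
        A = Xc.T @ Xc + 1e-6 * np.eye(p)
        beta[k] = np.linalg.solve(A, Xc.T @ yc)
        r = yc - Xc @ beta[k]
        resid_ss += (r**2).sum()
        resid_n += r.size
    sigma2 = max(resid_ss / max(resid_n, 1), 1e-3)
    pi = np.bincount(labels, minlength=K).astype(float) + 0.5
    pi /= pi.sum()
    Sigma_b = np.diag([max(0.25 * sigma2, 0.05), 0.02]) if has_re else None
    if has_re:
        sigma2 = max(sigma2 * 0.75, 1e-3)
    return pi, beta, Sigma_b, sigma2


def _random_start_labels(Yimp, K, rng, perturb=0.2):
    labels = _lloyd_kmeans(Yimp, K, rng)
    n = labels.size
    flip = rng.random(n) < perturb
    labels[flip] = rng.integers(0, K, size=int(flip.sum()))
    # every class must keep at least one member
    for k in range(K):
        if not (labels == k).any():
            labels[rng.integers(n)] = k
    return labels


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


def fit_gmm(
    data: Sequence[AnnualSeries] | np.ndarray,
    spec: GrowthMixtureSpec,
) -> GrowthMixtureFit:
    """Fit a growth mixture model by multi-start EM.

    ``data`` is a collection of annual series (or an n x T NaN-coded matrix).
    Exploratory starts use perturbed k-means initialisation and a short run
    of closed-form EM; the best few are refined to convergence and the
    highest-likelihood solution is returned with classes reordered by
    descending mixing proportion.
    """
    if isinstance(data, np.ndarray):
        Y = np.asarray(data, dtype=float)
        ids = [f"r{i}" for i in range(Y.shape[0])]
    else:
        ids, Y = annual_matrix(list(data))
    n, T = Y.shape
    K, p = spec.n_classes, spec.degree + 1
    X, Z = design_matrices(T, spec.degree)
    if n <= spec.n_params():
        warnings.warn(
            f"n={n} subjects is not larger than the parameter count {spec.n_params()}",
            stacklevel=2,
        )
    patterns = _build_patterns(Y, X, Z)
    rng = np.random.default_rng(spec.seed)

    obs = ~np.isnan(Y)
    row_mean = np.nanmean(Y, axis=1)
    Yimp = np.where(obs, Y, row_mean[:, None])

    n_starts = 1 if K == 1 else spec.n_starts
    short_states = []
    diagnostics = []
    for s in range(n_starts):
        state = None
        for attempt in range(3):
            if K == 1:
                labels = np.zeros(n, dtype=int)
            else:
                labels = _random_start_labels(Yimp, K, rng)
            init = _init_from_labels(Y, X, labels, K, p, spec.has_re, rng)
            try:
                params, ll, trace, conv, P = _em(
                    patterns, init, n, p, spec.has_re,
                    max_iter=spec.short_iter, tol=max(spec.tol, 1e-4),
                )
                state = (params, ll, trace, s)
                break
            except _DegenerateStart as exc:
                diagnostics.append(f"start {s} attempt {attempt}: {exc}")
        if state is not None:
            short_states.append(state)
        else:
            diagnostics.append(f"start {s}: abandoned after repeated degeneracy")
    if not short_states:
        # every exploratory start collapsed a class; keep one boundary run
        warnings.warn(
            "all exploratory starts degenerated; continuing without the "
            "class-share floor",
            stacklevel=2,
        )
        labels = (
            np.zeros(n, dtype=int) if K == 1 else _random_start_labels(Yimp, K, rng)
        )
        init = _init_from_labels(Y, X, labels, K, p, spec.has_re, rng)
        params, ll, trace, conv, P = _em(
            patterns, init, n, p, spec.has_re,
            max_iter=spec.short_iter, tol=max(spec.tol, 1e-4),
            check_degenerate=False,
        )
        short_states.append((params, ll, trace, 0))

    short_states.sort(key=lambda st: (-st[1], st[3]))
    best = None
    for params, ll_short, trace_short, s in short_states[: max(spec.n_final, 1)]:
        try:
            params_f, ll_f, trace_f, conv, P = _em(
                patterns, params, n, p, spec.has_re,
                max_iter=spec.max_iter, tol=spec.tol, refine=True,
            )
        except _DegenerateStart as exc:
            diagnostics.append(f"refinement of start {s}: {exc}")
            continue
        trace = np.concatenate([trace_short, trace_f[1:]])
        if best is None or ll_f > best[1] + 1e-10:
            best = (params_f, ll_f, trace, conv, P, s)
    if best is None:
        # every refinement collapsed a class below 1/n; accept the boundary
        # solution from the best short start rather than failing outright
        warnings.warn(
            "refined solutions kept a class share below 1/n; "
            "returning the boundary solution",
            stacklevel=2,
        )
        params, ll_short, trace_short, s = short_states[0]
        params_f, ll_f, trace_f, conv, P = _em(
            patterns, params, n, p, spec.has_re,
            max_iter=spec.max_iter, tol=spec.tol, refine=True,
            check_degenerate=False,
        )
        best = (params_f, ll_f, np.concatenate([trace_short, trace_f[1:]]), conv, P, s)

    (pi, beta, Sigma_b, sigma2), loglik, trace, converged, P, _ = best
    order = np.argsort(-pi, kind="stable")
    pi = pi[order]
    beta = beta[order]
    P = P[:, order]

    return GrowthMixtureFit(
        spec=spec,
        pi=pi,
        beta=beta,
        Sigma_b=Sigma_b,
        sigma2=float(sigma2),
        loglik=float(loglik),
        posteriors=P,
        n_params=spec.n_params(),
        converged=bool(converged),
        n_used=n,
        T=T,
        subject_ids=list(ids),
        loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# fit summaries
# ---------------------------------------------------------------------------


def compute_bic(loglik: float, n_params: int, n: int) -> float:
    """Bayesian information criterion, -2 L + p ln(n), n = number of subjects."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + n_params * np.log(n)


def compute_entropy(posteriors: np.ndarray) -> float:
    """Normalised classification entropy in [0, 1]; 1 = perfect separation.

    E = 1 - sum_ik(-p_ik ln p_ik) / (n ln K); undefined (NaN) for K = 1.
    """
    P = np.asarray(posteriors, dtype=float)
    n, K = P.shape
    if K < 2:
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log(P), 0.0)
    return float(1.0 - terms.sum() / (n * np.log(K)))


def avg_posterior_by_modal_class(posteriors: np.ndarray) -> np.ndarray:
    """Mean posterior probability of class k among subjects modally assigned
    to k; NaN for classes with no modal members."""
    P = np.asarray(posteriors, dtype=float)
    modal = P.argmax(axis=1)
    K = P.shape[1]
    out = np.full(K, np.nan)
    for k in range(K):
        members = modal == k
        if members.any():
            out[k] = P[members, k].mean()
    return out


# ---------------------------------------------------------------------------
# robust (sandwich) standard errors
# ---------------------------------------------------------------------------


@dataclass
class RobustSEResult:
    names: list[str]
    theta: np.ndarray
    se_robust: np.ndarray
    se_model: np.ndarray


def _pack_fit(fit: GrowthMixtureFit) -> tuple[np.ndarray, list[str]]:
    K, p = fit.beta.shape
    theta = [fit.beta.ravel()]
    names = [f"beta[{k}][{j}]" for k in range(K) for j in range(p)]
    if K > 1:
        theta.append(np.log(fit.pi[:-1] / fit.pi[-1]))
        names += [f"log_pi_ratio[{k}]" for k in range(K - 1)]
    theta.append([np.log(fit.sigma2)])
    names.append("log_sigma2")
    if fit.Sigma_b is not None:
        L = np.linalg.cholesky(fit.Sigma_b + 1e-12 * np.eye(2))
        theta.append([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])
        names += ["log_chol_b[0,0]", "chol_b[1,0]", "log_chol_b[1,1]"]
    return np.concatenate([np.atleast_1d(t) for t in theta]), names


def _unpack_theta(theta: np.ndarray, K: int, p: int, has_re: bool):
    i = K * p
    beta = theta[:i].reshape(K, p)
    if K > 1:
        eta = theta[i : i + K - 1]
        i += K - 1
        w = np.concatenate([np.exp(eta), [1.0]])
        pi = w / w.sum()
    else:
        pi = np.ones(1)
    sigma2 = float(np.exp(theta[i]))
    i += 1
    Sigma_b = None
    if has_re:
        L = np.array([[np.exp(theta[i]), 0.0], [theta[i + 1], np.exp(theta[i + 2])]])
        Sigma_b = L @ L.T
    return pi, beta, Sigma_b, sigma2


def robust_standard_errors(
    fit: GrowthMixtureFit,
    data: Sequence[AnnualSeries] | np.ndarray,
) -> RobustSEResult:
    """Sandwich standard errors A^-1 B A^-1 for the packed parameter vector.

    A is the observed-information approximation (numerical Hessian of the
    total log-likelihood) and B the outer product of per-subject score
    vectors obtained by central differencing.
    """
    if not fit.converged:
        raise ValueError("robust standard errors require a converged fit")
    if isinstance(data, np.ndarray):
        Y = np.asarray(data, dtype=float)
    else:
        _, Y = annual_matrix(list(data))
    n = Y.shape[0]
    K, p = fit.beta.shape
    X, Z = design_matrices(fit.T, fit.spec.degree)
    patterns = _build_patterns(Y, X, Z)

    def subj_logliks(theta: np.ndarray) -> np.ndarray:
        pi, beta, Sigma_b, sigma2 = _unpack_theta(theta, K, p, fit.spec.has_re)
        ll = _loglik_matrix(patterns, beta, Sigma_b, sigma2, n)
        return logsumexp(np.log(pi)[None, :] + ll, axis=1)

    theta0, names = _pack_fit(fit)
    d = theta0.size
    h = 1e-5 * np.maximum(1.0, np.abs(theta0))

    scores = np.empty((n, d))
    for j in range(d):
        tp, tm = theta0.copy(), theta0.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        scores[:, j] = (subj_logliks(tp) - subj_logliks(tm)) / (2 * h[j])
    B = scores.T @ scores

    def total(theta):
        return subj_logliks(theta).sum()

    A = np.empty((d, d))
    f0 = total(theta0)
    fp = np.empty(d)
    fm = np.empty(d)
    for j in range(d):
        tp, tm = theta0.copy(), theta0.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        fp[j] = total(tp)
        fm[j] = total(tm)
    for j in range(d):
        for l in range(j, d):
            if j == l:
                A[j, j] = (fp[j] - 2 * f0 + fm[j]) / h[j] ** 2
            else:
                tpp = theta0.copy()
                tpp[[j, l]] += [h[j], h[l]]
                tmm = theta0.copy()
                tmm[[j, l]] -= [h[j], h[l]]
                A[j, l] = A[l, j] = (
                    total(tpp) - fp[j] - fp[l] + 2 * f0 - fm[j] - fm[l] + total(tmm)
                ) / (2 * h[j] * h[l])
    A = -A  # observed information
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "observed information is not invertible; consider a simpler model"
        ) from exc
    cov_robust = Ainv @ B @ Ainv.T
    return RobustSEResult(
        names=names,
        theta=theta0,
        se_robust=np.sqrt(np.clip(np.diag(cov_robust), 0, None)),
        se_model=np.sqrt(np.clip(np.diag(Ainv), 0, None)),
    )


# ---------------------------------------------------------------------------
# simulation from a fit (parametric bootstrap support)
# ---------------------------------------------------------------------------


def simulate_from_fit(
    fit: GrowthMixtureFit,
    masks: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw an n x T outcome matrix from the fitted model, applying the given
    boolean observation masks (True = observed) to reproduce a missingness
    pattern."""
    n, T = masks.shape
    X, Z = design_matrices(T, fit.spec.degree)
    classes = rng.choice(fit.n_classes, size=n, p=fit.pi)
    mu = (fit.beta @ X.T)[classes]  # (n, T)
    if fit.Sigma_b is not None:
        L = np.linalg.cholesky(fit.Sigma_b + 1e-12 * np.eye(2))
        b = rng.standard_normal((n, 2)) @ L.T
        mu = mu + b @ Z.T
    Y = mu + rng.normal(0.0, np.sqrt(fit.sigma2), size=(n, T))
    Y[~masks] = np.nan
    return Y
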