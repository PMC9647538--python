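"""Baseline-covariate associations with trajectory class (pairwise logistic
regressions against the remitting reference), the random-intercept logistic
check of the missing-at-random assumption, and per-class outcome summaries."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, roots_hermitenorm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import AnnualSeries, MonthlyTimeline, aggregate_to_annual

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "class_association_or",
    "missingness_mar_check",
    "outcome_summaries",
    "random_intercept_logit",
]

#: covariates always adjusted for (dropped when one is itself the exposure)
DEFAULT_ADJUSTERS = ("centre", "sex", "age_at_onset", "ethnicity")

_CATEGORICAL = {
    "centre",
    "sex",
    "ethnicity",
    "education",
    "premorbid_iq_quartile",
    "diagnosis",
    "mode_of_onset",
}


@dataclass
class AssociationResult:
    covariate: str
    level: str | None  # non-reference level for categorical exposures
    comparison: str
    reference: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusters: tuple[str, ...]
    n_comparison: int
    n_reference: int

    def __post_init__(self) -> None:
        if np.isfinite(self.odds_ratio) and not (
            self.ci_low <= self.odds_ratio <= self.ci_high
        ):
            raise ValueError("confidence interval must bracket the odds ratio")


def _design_columns(df: pd.DataFrame, name: str) -> pd.DataFrame:
    """Encode one covariate as regression columns (dummies for categoricals)."""
    if name in _CATEGORICAL:
        d = pd.get_dummies(df[name].astype(str), prefix=name, drop_first=True)
        return d.astype(float)
    return df[[name]].astype(float)


def class_association_or(
    labels: Mapping[str, str] | pd.Series,
    baselines: pd.DataFrame,
    covariate: str,
    adjusters: Sequence[str] | None = None,
    comparison: str = "persistent",
    reference: str = "remitting",
) -> list[AssociationResult]:
    """Odds ratios for membership of ``comparison`` vs ``reference`` class.

    Binary logistic regression of modal class membership on the covariate
    plus adjusters (by default centre, sex, age and ethnicity, dropping the
    exposure itself), with Wald 95% confidence intervals.  Categorical
    exposures return one result per non-reference level.  Separation or an
    empty cell yields a NaN odds ratio with a warning.
    """
    lab = pd.Series(labels)
    if adjusters is None:
        adjusters = tuple(a for a in DEFAULT_ADJUSTERS if a != covariate)
    keep = lab[lab.isin([comparison, reference])]
    df = baselines.loc[baselines.index.intersection(keep.index)].copy()
    if df.empty:
        raise ValueError("labels and baseline table share no subject ids")
    y = (keep.loc[df.index] == comparison).astype(float)
    n_comp, n_ref = int(y.sum()), int((1 - y).sum())

    Xparts = [_design_columns(df, covariate)]
    for adj in adjusters:
        Xparts.append(_design_columns(df, adj))
    X = pd.concat(Xparts, axis=1)
    X.insert(0, "const", 1.0)
    exposure_cols = list(Xparts[0].columns)

    results = []
    try:
        if n_comp == 0 or n_ref == 0:
            raise PerfectSeparationError("empty comparison or reference cell")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y.to_numpy(), X.to_numpy())
            res = model.fit(disp=0, maxiter=200)
        params = pd.Series(res.params, index=X.columns)
        bse = pd.Series(res.bse, index=X.columns)
        pvals = pd.Series(res.pvalues, index=X.columns)
        if not res.mle_retvals.get("converged", True) or bse[exposure_cols].max() > 50:
            raise PerfectSeparationError("unstable fit (quasi-separation)")
        for col in exposure_cols:
            b, se = params[col], bse[col]
            level = col[len(covariate) + 1 :] if col != covariate else None
            results.append(
                AssociationResult(
                    covariate=covariate,
                    level=level,
                    comparison=comparison,
                    reference=reference,
                    odds_ratio=float(np.exp(b)),
                    ci_low=float(np.exp(b - 1.959963984540054 * se)),
                    ci_high=float(np.exp(b + 1.959963984540054 * se)),
                    p_value=float(pvals[col]),
                    adjusters=tuple(adjusters),
                    n_comparison=n_comp,
                    n_reference=n_ref,
                )
            )
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
        warnings.warn(
            f"association for {covariate!r} ({comparison} vs {reference}) "
            f"could not be estimated: {exc}",
            stacklevel=2,
        )
        for col in exposure_cols:
            level = col[len(covariate) + 1 :] if col != covariate else None
            results.append(
                AssociationResult(
                    covariate=covariate,
                    level=level,
                    comparison=comparison,
                    reference=reference,
                    odds_ratio=float("nan"),
                    ci_low=float("nan"),
                    ci_high=float("nan"),
                    p_value=float("nan"),
                    adjusters=tuple(adjusters),
                    n_comparison=n_comp,
                    n_reference=n_ref,
                )
            )
    return results


# ---------------------------------------------------------------------------
# random-intercept logistic regression (Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------


@dataclass
class RandomInterceptLogitResult:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    sigma_u: float
    loglik: float
    converged: bool


def random_intercept_logit(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    names: Sequence[str] | None = None,
    n_quad: int = 15,
) -> RandomInterceptLogitResult:
    """ML logistic regression with a group-level Gaussian random intercept.

    The marginal likelihood integrates the random intercept by probabilists'
    Gauss-Hermite quadrature.  Standard errors come from the numerical
    observed information.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    uniq, gidx = np.unique(groups, return_inverse=True)
    n_groups = uniq.size
    p = X.shape[1]
    nodes, wts = roots_hermitenorm(n_quad)
    logw = np.log(wts / np.sqrt(2.0 * np.pi))

    if y.min() == y.max():
        # degenerate outcome: nothing to estimate
        return RandomInterceptLogitResult(
            names=list(names or [f"x{j}" for j in range(p)]),
            coef=np.full(p, np.nan),
            se=np.full(p, np.nan),
            z=np.full(p, np.nan),
            p=np.full(p, np.nan),
            sigma_u=float("nan"),
            loglik=float("nan"),
            converged=False,
        )

    def negll(theta: np.ndarray) -> float:
        beta, log_su = theta[:p], theta[p]
        su = np.exp(np.clip(log_su, -10, 4))
        eta = X @ beta  # (N,)
        # (N, Q) linear predictors across quadrature nodes
        etaq = eta[:, None] + su * nodes[None, :]
        llobs = y[:, None] * etaq - np.logaddexp(0.0, etaq)
        llg = np.zeros((n_groups, n_quad))
        np.add.at(llg, gidx, llobs)
        return -float(logsumexp(llg + logw[None, :], axis=1).sum())

    theta0 = np.concatenate([np.zeros(p), [np.log(0.5)]])
    res = minimize(negll, theta0, method="BFGS", options={"maxiter": 500, "gtol": 1e-7})
    theta = res.x
    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(theta, negll)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
        ok = bool(res.success) or res.fun < negll(theta0)
    except np.linalg.LinAlgError:
        se_all = np.full(p + 1, np.nan)
        ok = False
    coef = theta[:p]
    se = se_all[:p]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = coef / se
    return RandomInterceptLogitResult(
        names=list(names or [f"x{j}" for j in range(p)]),
        coef=coef,
        se=se,
        z=z,
        p=2.0 * stats.norm.sf(np.abs(z)),
        sigma_u=float(np.exp(theta[p])),
        loglik=-float(res.fun),
        converged=ok,
    )


def missingness_mar_check(
    timelines: Mapping[str, MonthlyTimeline],
    baselines: pd.DataFrame,
    T: int = 10,
    covariates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Association of annual-timeline missingness with baseline covariates.

    Builds a per-subject-year missing indicator from the annual aggregation
    and fits, per covariate, a logistic model with a subject-level random
    intercept.  Returns one row per covariate term with coefficient, SE and
    p.  Non-convergent (or degenerate, e.g. zero-missingness) models are
    flagged rather than raised.
    """
    if covariates is None:
        covariates = [
            "centre",
            "sex",
            "age_at_onset",
            "ethnicity",
            "education",
            "disadvantage_index",
            "premorbid_iq_quartile",
            "diagnosis",
            "dup_months",
            "mode_of_onset",
        ]
    sids = [s for s in timelines if s in baselines.index]
    if not sids:
        raise ValueError("no overlap between timelines and baseline table")
    miss_rows = []
    for sid in sids:
        ann = aggregate_to_annual(timelines[sid], T=T)
        for t in range(T):
            miss_rows.append((sid, t + 1, float(np.isnan(ann.y[t]))))
    long = pd.DataFrame(miss_rows, columns=["subject_id", "year", "missing"])
    bl = baselines.loc[sids]

    records = []
    for cov in covariates:
        cols = _design_columns(bl, cov)
        merged = long.merge(cols, left_on="subject_id", right_index=True, how="left")
        X = np.column_stack(
            [np.ones(len(merged))] + [merged[c].to_numpy(dtype=float) for c in cols.columns]
        )
        res = random_intercept_logit(
            merged["missing"].to_numpy(),
            X,
            merged["subject_id"].to_numpy(),
            names=["const"] + list(cols.columns),
        )
        for j, term in enumerate(res.names):
            if term == "const":
                continue
            records.append(
                {
                    "covariate": cov,
                    "term": term,
                    "coef": res.coef[j],
                    "se": res.se[j],
                    "z": res.z[j],
                    "p": res.p[j],
                    "sigma_u": res.sigma_u,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(records)


def outcome_summaries(
    labels: Mapping[str, str] | pd.Series,
    outcomes: pd.DataFrame,
) -> dict:
    """Per-class GAF-D mean/SD/n, binary outcome proportions, and the one-way
    ANOVA F test for GAF-D across classes."""
    lab = pd.Series(labels, name="trajectory_class")
    common = lab.index.intersection(outcomes.index)
    if len(common) == 0:
        raise ValueError("labels and outcome table share no subject ids")
    df = outcomes.loc[common].copy()
    df["trajectory_class"] = lab.loc[common]

    gaf = df.dropna(subset=["gaf_d"])
    grp = gaf.groupby("trajectory_class")["gaf_d"]
    gaf_summary = grp.agg(mean="mean", sd="std", n="count")
    gaf_summary.loc[gaf_summary["n"] < 2, "sd"] = np.nan

    groups = [g.to_numpy() for _, g in grp if len(g) >= 2]
    if len(groups) >= 2:
        F, pval = stats.f_oneway(*groups)
        anova = {"F": float(F), "df_between": len(groups) - 1, "p": float(pval)}
    else:
        anova = {"F": float("nan"), "df_between": float("nan"), "p": float("nan")}

    binary = {}
    for col in ("in_relationship", "employed"):
        if col in df:
            sub = df.dropna(subset=[col])
            if len(sub):
                binary[col] = (
                    sub.groupby("trajectory_class")[col]
                    .agg(proportion="mean", n="count")
                )
    return {"gaf_d": gaf_summary, "anova_gaf_d": anova, "binary": binary}
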