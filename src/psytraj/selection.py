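"""Model ladder, likelihood-ratio class-enumeration tests, final-model
selection rules, and trajectory-class labelling."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cohort import AnnualSeries, annual_matrix
from .gmm import (
    GrowthMixtureFit,
    GrowthMixtureSpec,
    avg_posterior_by_modal_class,
    compute_bic,
    compute_entropy,
    design_matrices,
    fit_gmm,
    simulate_from_fit,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LadderRow",
    "ModelLadderResult",
    "SelectionRules",
    "run_model_ladder",
    "lmr_test",
    "bootstrap_lrt",
    "blrt_pvalue",
    "select_final_model",
    "label_classes",
]

CANONICAL_LABELS = ("remitting", "late_decline", "late_improvement", "persistent")


@dataclass
class LadderRow:
    spec: GrowthMixtureSpec
    converged: bool
    loglik: float = float("nan")
    n_params: int = 0
    bic: float = float("nan")
    entropy: float = float("nan")
    min_class_share: float = float("nan")
    avg_posteriors: np.ndarray | None = None
    fit: GrowthMixtureFit | None = None
    error: str | None = None

    def describe(self) -> str:
        re = "is" if self.spec.has_re else "none"
        return f"K={self.spec.n_classes} degree={self.spec.degree} re={re}"


@dataclass
class ModelLadderResult:
    rows: list[LadderRow]
    selected: int | None = None
    selection_trace: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, r in enumerate(self.rows):
            recs.append(
                {
                    "index": i,
                    "n_classes": r.spec.n_classes,
                    "degree": r.spec.degree,
                    "random_effects": r.spec.random_effects,
                    "converged": r.converged,
                    "loglik": r.loglik,
                    "n_params": r.n_params,
                    "bic": r.bic,
                    "entropy": r.entropy,
                    "min_class_share": r.min_class_share,
                    "selected": i == self.selected,
                }
            )
        return pd.DataFrame(recs).set_index("index")


@dataclass
class SelectionRules:
    """Decision rules for the final model."""

    delta_bic: float = 10.0  # a BIC advantage of >= this is decisive
    min_class_share: float = 0.05  # reject solutions with a smaller class


def default_grid(
    degrees: Sequence[int] = (1, 2),
    random_effects: Sequence[str] = ("none", "intercept_slope"),
    class_range: Sequence[int] = (1, 2, 3, 4, 5, 6),
) -> list[dict]:
    return [
        {"degree": d, "random_effects": re, "n_classes": k}
        for d, re, k in product(degrees, random_effects, class_range)
    ]


def run_model_ladder(
    data: Sequence[AnnualSeries] | np.ndarray,
    grid: Sequence[dict] | None = None,
    base_spec: GrowthMixtureSpec | None = None,
) -> ModelLadderResult:
    """Fit every model in the grid; failures are recorded, not fatal."""
    if grid is None:
        grid = default_grid()
    base = base_spec or GrowthMixtureSpec()
    rows: list[LadderRow] = []
    for cell in grid:
        spec = replace(base, **cell)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_gmm(data, spec)
            rows.append(
                LadderRow(
                    spec=spec,
                    converged=fit.converged,
                    loglik=fit.loglik,
                    n_params=fit.n_params,
                    bic=fit.bic,
                    entropy=fit.entropy,
                    min_class_share=fit.min_class_share,
                    avg_posteriors=avg_posterior_by_modal_class(fit.posteriors),
                    fit=fit,
                )
            )
        except Exception as exc:  # recorded per cell
            logger.warning("ladder cell %s failed: %s", cell, exc)
            rows.append(LadderRow(spec=spec, converged=False, error=str(exc)))
    if not any(r.converged for r in rows):
        raise RuntimeError("every ladder cell failed to converge")
    return ModelLadderResult(rows=rows)


def lmr_test(
    fit_k: GrowthMixtureFit,
    fit_k_minus_1: GrowthMixtureFit,
    n: int,
) -> tuple[float, float]:
    """Adjusted likelihood-ratio class-enumeration test (k vs k-1 classes).

    The raw statistic 2(L_k - L_{k-1}) is shrunk by the sample-size
    correction factor c = 1 + 1/(dp * ln n), dp the parameter-count
    difference, and referred to a chi-square with 2*dp degrees of freedom.
    This reference is deliberately conservative for mixture enumeration;
    small p favours the k-class model.
    """
    stat = 2.0 * (fit_k.loglik - fit_k_minus_1.loglik)
    dp = fit_k.n_params - fit_k_minus_1.n_params
    if dp <= 0:
        raise ValueError("fit_k must have more parameters than fit_k_minus_1")
    if stat < 0:
        warnings.warn(
            "log-likelihood decreased when adding a class; optimisation failure suspected",
            stacklevel=2,
        )
        return float(stat), float("nan")
    c = 1.0 + 1.0 / (dp * np.log(n))
    adj = stat / c
    p = float(chi2.sf(adj, df=2 * dp))
    return float(adj), p


def blrt_pvalue(lr_obs: float, lr_draws: Sequence[float]) -> float:
    """Add-one bootstrap p-value, (1 + #{LR_b >= LR_obs}) / (B + 1)."""
    lrs = np.asarray(lr_draws, dtype=float)
    if lrs.size < 1:
        raise ValueError("at least one bootstrap draw is required")
    return float((1.0 + (lrs >= lr_obs).sum()) / (lrs.size + 1.0))


def bootstrap_lrt(
    data: Sequence[AnnualSeries] | np.ndarray,
    spec_k: GrowthMixtureSpec,
    spec_k_minus_1: GrowthMixtureSpec,
    B: int = 500,
    seed: int = 0,
    bootstrap_starts: int = 10,
) -> tuple[float, float]:
    """Parametric-bootstrap likelihood ratio test for k vs k-1 classes.

    B datasets are simulated from the fitted (k-1)-class model with the
    observed missingness pattern; both models are refitted to each and
    p = (1 + #{LR_b >= LR_obs}) / (B_ok + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if isinstance(data, np.ndarray):
        Y = np.asarray(data, dtype=float)
    else:
        _, Y = annual_matrix(list(data))
    masks = ~np.isnan(Y)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_null = fit_gmm(Y, spec_k_minus_1)
        fit_alt = fit_gmm(Y, spec_k)
    lr_obs = max(2.0 * (fit_alt.loglik - fit_null.loglik), 0.0)

    # bootstrap refits trade precision for speed: the LR null draws only need
    # to be resolved to ~1e-2
    _fast = dict(tol=max(spec_k.tol, 5e-4), max_iter=150, short_iter=25, n_final=2)
    boot_k = replace(spec_k, n_starts=min(bootstrap_starts, spec_k.n_starts), **_fast)
    boot_km1 = replace(
        spec_k_minus_1, n_starts=min(bootstrap_starts, spec_k_minus_1.n_starts), **_fast
    )
    rng = np.random.default_rng(seed)
    lrs = []
    failures = 0
    for b in range(B):
        Yb = simulate_from_fit(fit_null, masks, rng)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f0 = fit_gmm(Yb, replace(boot_km1, seed=seed + 1000 + b))
                f1 = fit_gmm(Yb, replace(boot_k, seed=seed + 1000 + b))
            lrs.append(max(2.0 * (f1.loglik - f0.loglik), 0.0))
        except Exception as exc:
            failures += 1
            logger.warning("bootstrap draw %d failed: %s", b, exc)
    if failures > 0.1 * B:
        raise RuntimeError(f"{failures} of {B} bootstrap fits failed")
    if failures:
        warnings.warn(f"dropped {failures} failed bootstrap draws", stacklevel=2)
    return float(lr_obs), blrt_pvalue(lr_obs, lrs)


def select_final_model(
    ladder: ModelLadderResult,
    rules: SelectionRules | None = None,
) -> tuple[int, list[str]]:
    """Apply the selection rules to a ladder table.

    Among converged rows: rows whose smallest class share is below the
    threshold are rejected; the remaining rows within ``delta_bic`` of the
    best BIC are kept and ranked by higher entropy, then fewer classes.  If
    no row passes the class-share rule, the best-BIC row overall is returned
    with a prominent warning.  Pure function of the table: the trace records
    every rule firing.
    """
    rules = rules or SelectionRules()
    trace: list[str] = []
    converged = [(i, r) for i, r in enumerate(ladder.rows) if r.converged]
    if not converged:
        raise ValueError("ladder has no converged rows")

    passing = []
    for i, r in converged:
        if np.isfinite(r.min_class_share) and r.min_class_share < rules.min_class_share:
            trace.append(
                f"row {i} ({r.describe()}): rejected, smallest class share "
                f"{r.min_class_share:.3f} < {rules.min_class_share:.2f}"
            )
        else:
            passing.append((i, r))

    if not passing:
        i_best = min(converged, key=lambda ir: ir[1].bic)[0]
        msg = (
            "no converged model satisfies the minimum class-share rule; "
            f"falling back to the best-BIC row {i_best}"
        )
        warnings.warn(msg, stacklevel=2)
        trace.append(msg)
        ladder.selected = i_best
        ladder.selection_trace = trace
        return i_best, trace

    i_best, r_best = min(passing, key=lambda ir: ir[1].bic)
    trace.append(f"row {i_best} ({r_best.describe()}): best BIC {r_best.bic:.2f}")
    survivors = []
    for i, r in passing:
        d = r.bic - r_best.bic
        if d >= rules.delta_bic:
            trace.append(
                f"row {i} ({r.describe()}): rejected, BIC disadvantage "
                f"{d:.1f} >= {rules.delta_bic:.0f}"
            )
        else:
            survivors.append((i, r))

    def rank(ir):
        i, r = ir
        ent = r.entropy if np.isfinite(r.entropy) else -np.inf
        return (-ent, r.spec.n_classes, r.bic, i)

    survivors.sort(key=rank)
    i_sel, r_sel = survivors[0]
    if len(survivors) > 1:
        trace.append(
            f"row {i_sel} ({r_sel.describe()}): preferred among "
            f"{len(survivors)} near-equivalent rows (entropy "
            f"{r_sel.entropy:.3f}, {r_sel.spec.n_classes} classes)"
        )
    trace.append(f"selected row {i_sel} ({r_sel.describe()})")
    ladder.selected = i_sel
    ladder.selection_trace = trace
    return i_sel, trace


def label_classes(fit: GrowthMixtureFit, high_threshold: float = 6.0) -> dict[int, str]:
    """Name the classes of a 4-class fit from their fitted mean curves.

    A class is "high" early (years 1-3) and/or late (years 8-10, or the last
    three follow-up years) if the corresponding mean exceeds
    ``high_threshold`` months per year.  low/low -> remitting, low/high ->
    late_decline, high/low -> late_improvement, high/high -> persistent.
    Non-4-class fits get generic labels; duplicated names are suffixed.
    """
    K = fit.n_classes
    if K != 4:
        return {k: f"class_{k + 1}" for k in range(K)}
    curves = fit.mean_curves()  # (K, T)
    T = curves.shape[1]
    early = curves[:, : min(3, T)].mean(axis=1)
    late = curves[:, max(T - 3, 0):].mean(axis=1)

    labels: dict[int, str] = {}
    for k in range(K):
        hi_e = early[k] > high_threshold
        hi_l = late[k] > high_threshold
        if hi_e and hi_l:
            labels[k] = "persistent"
        elif hi_e and not hi_l:
            labels[k] = "late_improvement"
        elif not hi_e and hi_l:
            labels[k] = "late_decline"
        else:
            labels[k] = "remitting"

    seen: dict[str, int] = {}
    for k in sorted(labels):
        name = labels[k]
        seen[name] = seen.get(name, 0) + 1
    dupes = {name for name, cnt in seen.items() if cnt > 1}
    if dupes:
        warnings.warn(
            f"multiple classes mapped to the same label(s): {sorted(dupes)}; "
            "suffix-indexing applied",
            stacklevel=2,
        )
        counters: dict[str, int] = {}
        for k in sorted(labels):
            name = labels[k]
            if name in dupes:
                counters[name] = counters.get(name, 0) + 1
                labels[k] = f"{name}_{counters[name]}"
    return labels
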